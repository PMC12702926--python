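"""Post-prediction triage: applicability domain, drug-likeness, synthesizability.

Raw classifier probabilities are turned into a ranked candidate list by a
fixed-order funnel: activity (p ≥ 0.5) → applicability domain (max Tanimoto
to the training set ≥ 0.4) → drug-likeness (QED ≥ 0.7) → synthetic
accessibility (SA ≤ 3).  The applicability domain deliberately uses the
ENTIRE training set (actives and inactives): it bounds where the model has
seen chemistry at all, not where it has seen activity.
"""

from __future__ import annotations

import sys
import os
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import QED as _QED

from .chemio import ConfigurationError, InputError, MoleculeRecord

_sascorer = None


def _default_sa_scorer() -> Callable[[Chem.Mol], float]:
    """The packaged Ertl fragment-contribution SA scorer (RDKit contrib)."""
    global _sascorer
    if _sascorer is None:
        from rdkit.Chem import RDConfig

        sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if not os.path.isdir(sa_dir):
            raise ConfigurationError(
                "SA fragment-contribution table not found (RDKit contrib SA_Score)"
            )
        if sa_dir not in sys.path:
            sys.path.append(sa_dir)
        import sascorer  # noqa: deferred heavy import

        _sascorer = sascorer
    return _sascorer.calculateScore


@dataclass(frozen=True)
class TriageThresholds:
    prob_min: float = 0.5
    tanimoto_min: float = 0.4
    qed_min: float = 0.7
    sa_max: float = 3.0

    def __post_init__(self):
        if not 0 <= self.prob_min <= 1:
            raise ValueError("prob_min must be in [0, 1]")
        if not 0 <= self.tanimoto_min <= 1:
            raise ValueError("tanimoto_min must be in [0, 1]")
        if not 0 <= self.qed_min <= 1:
            raise ValueError("qed_min must be in [0, 1]")
        if not 1 <= self.sa_max <= 10:
            raise ValueError("sa_max must be in [1, 10]")


@dataclass
class ScreeningRecord:
    id: str
    smiles: str
    probability: float
    max_tanimoto: float
    qed: Optional[float]
    sa: Optional[float]
    pass_activity: bool
    pass_ad: bool
    pass_qed: bool
    pass_sa: bool
    final_pass: bool


@dataclass
class FunnelReport:
    """Per-stage survival counts of the screening funnel.

    ``survivors[i]`` is the count alive after stage i (in configured order);
    ``excluded[i]`` the count removed at stage i; ``exclusion_pct[i]`` the
    percentage removed relative to the stage's own input.
    """

    n_input: int
    stage_order: list[str]
    survivors: list[int]
    excluded: list[int]
    exclusion_pct: list[float]

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stage_order": self.stage_order,
            "survivors": self.survivors,
            "excluded": self.excluded,
            "exclusion_pct": self.exclusion_pct,
        }


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length bit vectors.

    Defined as 1.0 for two all-zero vectors (identical empty sets).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


def max_similarity_to_set(
    query: np.ndarray,
    reference_set: np.ndarray,
    reference_ids: Optional[Sequence[str]] = None,
) -> tuple[float, int | str]:
    """Exact maximum Tanimoto of ``query`` over every reference fingerprint.

    A full linear scan (vectorized), never an approximate neighbor search.
    Returns (max value, argmax id or row index).
    """
    ref = np.asarray(reference_set, dtype=bool)
    if ref.ndim != 2 or ref.shape[0] == 0:
        raise InputError("reference set must be a non-empty 2D bit matrix")
    q = np.asarray(query, dtype=bool)
    if q.shape[0] != ref.shape[1]:
        raise InputError("query/reference fingerprint length mismatch")
    inter = (ref & q).sum(axis=1)
    union = (ref | q).sum(axis=1)
    sims = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    best = int(np.argmax(sims))
    best_id = reference_ids[best] if reference_ids is not None else best
    return float(sims[best]), best_id


def bulk_max_similarity(queries: np.ndarray, reference_set: np.ndarray) -> np.ndarray:
    """Max Tanimoto of each query row against the whole reference set."""
    Q = np.asarray(queries, dtype=np.float64)
    R = np.asarray(reference_set, dtype=np.float64)
    inter = Q @ R.T
    pq = Q.sum(axis=1)[:, None]
    pr = R.sum(axis=1)[None, :]
    union = pq + pr - inter
    sims = np.where(union == 0, 1.0, inter / np.maximum(union, 1e-300))
    return sims.max(axis=1)


# ---------------------------------------------------------------------------
# drug-likeness and synthesizability
# ---------------------------------------------------------------------------

def qed(mol: Chem.Mol, weighted: bool = True) -> float:
    """Quantitative estimate of drug-likeness in [0, 1].

    Weighted geometric mean of the eight desirability functions (MW, ALOGP,
    HBA, HBD, PSA, rotatable bonds, aromatic rings, structural alerts); the
    unweighted mean variant is available via ``weighted=False``.
    """
    if mol is None:
        raise InputError("qed: invalid molecule")
    return float(_QED.weights_mean(mol) if weighted else _QED.weights_none(mol))


def sa_score(
    mol: Chem.Mol, scorer: Optional[Callable[[Chem.Mol], float]] = None
) -> float:
    """Synthetic-accessibility score in [1, 10], 1 = easy to make.

    Fragment-frequency contributions plus complexity penalties (ring fusion,
    stereocentres, macrocycles, size).  ``scorer`` lets an alternative
    implementation be plugged in; the result is clamped into [1, 10].
    """
    if mol is None:
        raise InputError("sa_score: invalid molecule")
    fn = scorer if scorer is not None else _default_sa_scorer()
    return float(min(10.0, max(1.0, fn(mol))))


# ---------------------------------------------------------------------------
# the funnel
# ---------------------------------------------------------------------------

STAGES = ["activity", "ad", "qed", "sa"]


def run_funnel(
    records: Sequence[MoleculeRecord],
    probabilities: Sequence[float],
    training_fps: np.ndarray,
    thresholds: TriageThresholds = TriageThresholds(),
    fp_spec=None,
    sa_scorer: Optional[Callable[[Chem.Mol], float]] = None,
) -> tuple[list[ScreeningRecord], FunnelReport]:
    """Apply the four-stage triage funnel and rank the survivors.

    All four flags are computed for every compound (they are independent
    facts about it); the FunnelReport counts sequential survival in the fixed
    stage order activity → AD → QED → SA.  Survivors are ranked by
    probability descending, ties broken by id.
    """
    from .screenmodel import FingerprintSpec, featurize  # local import, no cycle

    if len(records) != len(probabilities):
        raise InputError("records and probabilities differ in length")
    spec = fp_spec if fp_spec is not None else FingerprintSpec()
    fps, skipped = featurize(records, spec)
    if skipped:
        raise InputError(f"unfingerprintable records at indices {skipped}")
    max_sims = bulk_max_similarity(fps, training_fps)

    out: list[ScreeningRecord] = []
    for rec, p, sim in zip(records, probabilities, max_sims):
        try:
            q = qed(rec.mol)
        except Exception:
            q = None
        try:
            s = sa_score(rec.mol, scorer=sa_scorer)
        except Exception:
            s = None
        pa = bool(p >= thresholds.prob_min)
        pad = bool(sim >= thresholds.tanimoto_min)
        pq = q is not None and q >= thresholds.qed_min
        ps = s is not None and s <= thresholds.sa_max
        out.append(
            ScreeningRecord(
                id=rec.id, smiles=rec.smiles,
                probability=float(p), max_tanimoto=float(sim), qed=q, sa=s,
                pass_activity=pa, pass_ad=pad, pass_qed=pq, pass_sa=ps,
                final_pass=pa and pad and pq and ps,
            )
        )

    flags = {
        "activity": np.array([r.pass_activity for r in out]),
        "ad": np.array([r.pass_ad for r in out]),
        "qed": np.array([r.pass_qed for r in out]),
        "sa": np.array([r.pass_sa for r in out]),
    }
    alive = np.ones(len(out), dtype=bool)
    survivors, excluded, pct = [], [], []
    for stage in STAGES:
        n_in = int(alive.sum())
        alive = alive & flags[stage]
        n_out = int(alive.sum())
        survivors.append(n_out)
        excluded.append(n_in - n_out)
        pct.append(100.0 * (n_in - n_out) / n_in if n_in else 0.0)
    report = FunnelReport(
        n_input=len(out), stage_order=list(STAGES),
        survivors=survivors, excluded=excluded, exclusion_pct=pct,
    )
    out.sort(key=lambda r: (-r.probability, r.id))
    return out, report


def stage_exclusion_pct(n_in: int, n_excluded: int) -> float:
    """Exclusion percentage of one funnel stage (e.g. 1245/5565 → 22.4)."""
    if n_in <= 0:
        raise InputError("stage input count must be positive")
    return 100.0 * n_excluded / n_in
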