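"""Deterministic synthetic data with known ground truth for every stage.

Real counterparts of the pipeline's inputs (curated bioactivity sets, docked
and aligned ligand libraries, docking scores) are either proprietary or not
deposited, so each generator here builds a structurally equivalent stand-in
whose expected outcome is known by construction:

* ``make_aligned_set`` — k para-substituted benzyl ligands sharing literal,
  exactly superimposed scaffold coordinates, with a manifest of every hybrid
  a correct fragment-swapper must produce (enumerated from string templates,
  independently of the hybridization code).
* ``make_activity_dataset`` — actives grown around a planted substructure
  motif, motif-free decoys, optional label noise; separable in ECFP4 space
  by construction when noise is zero.
* ``make_funnel_library`` — compounds drawn from category exemplars with
  known QED/SA/applicability-domain behaviour so that exactly the planted
  number survives each triage stage.
* ``make_ranked_screen`` — score/label vectors of chosen quality (perfect,
  random, worst, exponential) with closed-form expected enrichment behaviour.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import QED as _QED
from rdkit.Geometry import Point3D

from .chemio import InputError, MoleculeRecord, canonical_smiles
from .rankmetrics import RankedScreen
from .triage import FunnelReport, sa_score, tanimoto


class InfeasiblePlantError(ValueError):
    """The requested planted outcome cannot be realized by the generator."""


@dataclass(frozen=True)
class FixtureSpec:
    """Shared knobs for the synthetic generators."""

    seed: int = 0
    n_active: int = 600
    n_inactive: int = 600
    motif: str = "Nc1nc2ccccc2s1"  # 2-aminobenzothiazole
    scaffold: str = "benzyl"
    tails: tuple[str, ...] = ("O", "N", "S", "C")
    noise_rate: float = 0.0

    def __post_init__(self):
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# aligned 3D ligand sets for hybridization
# ---------------------------------------------------------------------------

_HALIDES = ("F", "Cl", "Br", "I")
#: tail heavy atom appended to the benzylic carbon, by element symbol
_TAIL_SMILES = {"O": "CO", "N": "CN", "S": "CS", "C": "CC"}

# literal scaffold coordinates (Å): benzene hexagon in the xy-plane, halogen
# para, benzylic CH2 and one tail heavy atom; identical for every ligand so
# cut-bond endpoints superimpose exactly
_RING = [
    (1.390, 0.000, 0.0),
    (0.695, 1.204, 0.0),
    (-0.695, 1.204, 0.0),
    (-1.390, 0.000, 0.0),
    (-0.695, -1.204, 0.0),
    (0.695, -1.204, 0.0),
]
_X_POS = (-2.870, 0.000, 0.0)   # halogen on C4
_CH2_POS = (2.900, 0.000, 0.0)  # benzylic carbon on C1
_TAIL_POS = (3.600, 1.250, 0.0)


def _build_aligned_ligand(halide: str, tail: str) -> Chem.Mol:
    """One rigid ligand: halide–C6H4–CH2–tail with the literal coordinates."""
    rw = Chem.RWMol()
    for _ in range(6):
        rw.AddAtom(Chem.Atom(6))
    x_idx = rw.AddAtom(Chem.Atom(halide))
    ch2_idx = rw.AddAtom(Chem.Atom(6))
    tail_idx = rw.AddAtom(Chem.Atom(tail))
    # kekulized ring; aromaticity is perceived on sanitization
    kinds = [Chem.BondType.DOUBLE, Chem.BondType.SINGLE] * 3
    for i in range(6):
        rw.AddBond(i, (i + 1) % 6, kinds[i])
    rw.AddBond(3, x_idx, Chem.BondType.SINGLE)
    rw.AddBond(0, ch2_idx, Chem.BondType.SINGLE)
    rw.AddBond(ch2_idx, tail_idx, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    coords = _RING + [_X_POS, _CH2_POS, _TAIL_POS]
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(x, y, z))
    mol.AddConformer(conf)
    return mol


def make_aligned_set(
    k: int = 4,
    tails: Optional[Sequence[str]] = None,
    perturb_ligand: Optional[int] = None,
    perturb_delta: float = 1.5,
) -> tuple[list[MoleculeRecord], list[str]]:
    """k aligned analogues plus the manifest of expected novel hybrids.

    Ligand i is ``X_i–C6H4–CH2–T_i`` with distinct halide head markers X and
    tail heteroatoms T.  At ``min_fragment_heavy_atoms=2`` the only cuttable
    bond is ring→CH2, its endpoints coincide exactly across ligands, and the
    complete hybrid set is therefore every head/tail cross ``X_i···T_j`` with
    i ≠ j: k·(k−1) novel molecules, enumerated here from string templates
    (never from the hybridization code).

    ``perturb_ligand`` shifts that ligand's CH2 endpoint by ``perturb_delta``
    Å out of plane, pushing its cut bond outside a 1.0 Å tolerance.
    """
    if not 2 <= k <= 4:
        raise InputError("aligned fixture supports 2 <= k <= 4 ligands")
    tails = tuple(tails) if tails is not None else ("O", "N", "S", "C")[:k]
    if len(tails) != k or len(set(tails)) != k:
        raise InputError("need k distinct tails")
    halides = _HALIDES[:k]

    records = []
    for i, (x, t) in enumerate(zip(halides, tails)):
        mol = _build_aligned_ligand(x, t)
        if perturb_ligand == i:
            conf = mol.GetConformer()
            p = conf.GetAtomPosition(7)  # the benzylic CH2
            conf.SetAtomPosition(7, Point3D(p.x, p.y, p.z + perturb_delta))
        records.append(
            MoleculeRecord(
                id=f"lig{i}", smiles=canonical_smiles(mol), mol=mol,
                provenance="fixtures:aligned",
            )
        )

    manifest = []
    active = [i for i in range(k) if i != perturb_ligand]
    for i in active:
        for j in active:
            if i == j:
                continue
            smi = f"{halides[i]}c1ccc({_TAIL_SMILES[tails[j]]})cc1"
            manifest.append(canonical_smiles(Chem.MolFromSmiles(smi)))
    return records, sorted(set(manifest))


# ---------------------------------------------------------------------------
# planted-motif activity datasets
# ---------------------------------------------------------------------------

_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCO", "CO", "OC", "OCC", "N(C)C", "F", "Cl", "Br",
    "C(F)(F)F", "C(=O)O", "C(=O)N", "CN", "CCN", "c2ccccc2", "c2ccncc2",
    "CC(C)C", "S(C)(=O)=O", "C#N", "CCCO", "OC(C)C", "C2CC2", "C(C)=O",
)

_ACTIVE_TEMPLATES = (
    "Nc1nc2cc({r1})ccc2s1",
    "N({r1})c1nc2ccccc2s1",
    "N({r1})c1nc2cc({r2})ccc2s1",
    "Nc1nc2cc({r1})c({r2})cc2s1",
)

_INACTIVE_TEMPLATES = (
    "c1cc({r1})ccc1{r2}",
    "c1cc({r1})cnc1{r2}",
    "O=C({r1})N{r2}",
    "C({r1})CCC{r2}",
    "c1cc({r1})oc1{r2}",
)


def make_activity_dataset(spec: FixtureSpec = FixtureSpec()) -> pd.DataFrame:
    """Labelled SMILES table: motif-bearing actives vs motif-free decoys.

    Columns (id, smiles, label).  Before label noise, every active contains
    ``spec.motif`` as a substructure and no inactive does, so the classes are
    separable in ECFP4 space; ``noise_rate`` then flips that fraction of
    labels.  Pure function of ``spec.seed``.
    """
    motif = Chem.MolFromSmiles(spec.motif)
    if motif is None:
        raise InputError(f"unparseable motif {spec.motif!r}")
    rng = np.random.default_rng(spec.seed)

    def grow(templates, want_motif: bool, n: int) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        tries = 0
        while len(out) < n:
            tries += 1
            if tries > 200 * n:
                raise InputError("fixture vocabulary exhausted; lower the count")
            tmpl = templates[rng.integers(len(templates))]
            smi = tmpl.format(
                r1=_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))],
                r2=_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))],
            )
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            if mol.HasSubstructMatch(motif) != want_motif:
                continue  # rejection-sample accidental motif hits in decoys
            can = canonical_smiles(mol)
            if can in seen:
                continue
            seen.add(can)
            out.append(can)
        return out

    actives = grow(_ACTIVE_TEMPLATES, True, spec.n_active)
    inactives = grow(_INACTIVE_TEMPLATES, False, spec.n_inactive)
    smiles = actives + inactives
    labels = np.array([1] * len(actives) + [0] * len(inactives))
    if spec.noise_rate > 0:
        n_flip = int(round(spec.noise_rate * len(labels)))
        flip = rng.choice(len(labels), size=n_flip, replace=False)
        labels[flip] = 1 - labels[flip]
    return pd.DataFrame(
        {
            "id": [f"cmp{i:05d}" for i in range(len(smiles))],
            "smiles": smiles,
            "label": labels,
        }
    )


def records_from_table(df: pd.DataFrame, provenance: str = "fixtures") -> list[MoleculeRecord]:
    """Materialize a fixtures table into MoleculeRecords (all rows parseable)."""
    recs = []
    for _, row in df.iterrows():
        mol = Chem.MolFromSmiles(row["smiles"])
        recs.append(
            MoleculeRecord(
                id=str(row["id"]), smiles=canonical_smiles(mol), mol=mol,
                label=int(row["label"]) if "label" in df.columns else None,
                provenance=provenance,
            )
        )
    return recs


def make_duplicate_library(n: int = 200, dup_fraction: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Unlabelled library with an exact planted number of duplicate rows."""
    n_dups = int(round(dup_fraction * n))
    base = make_activity_dataset(
        FixtureSpec(seed=seed, n_active=max(1, (n - n_dups) // 2),
                    n_inactive=n - n_dups - max(1, (n - n_dups) // 2))
    ).drop(columns=["label"])
    rng = np.random.default_rng(seed + 1)
    dup_rows = base.iloc[rng.integers(0, len(base), size=n_dups)].copy()
    df = pd.concat([base, dup_rows], ignore_index=True)
    df["id"] = [f"cmp{i:05d}" for i in range(len(df))]
    return df


# ---------------------------------------------------------------------------
# funnel libraries with planted stage survival
# ---------------------------------------------------------------------------

#: category exemplars: (smiles, passes activity, AD, QED, SA)
_FUNNEL_EXEMPLARS = {
    "fail_activity": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                       # caffeine
    "fail_ad": "FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",                  # perfluoropentane
    "fail_qed": "CCCCCCCCCCCCCCCCCC(=O)O",                               # stearic acid
    "fail_sa": "CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5",  # morphine
    "pass_all": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                            # ibuprofen
}


def make_funnel_library(
    planted_counts: Sequence[int], seed: int = 0
) -> tuple[list[MoleculeRecord], np.ndarray, list[MoleculeRecord], FunnelReport]:
    """A screening library whose funnel outcome is planted exactly.

    ``planted_counts = (n_total, after_activity, after_ad, after_qed,
    after_sa)``, non-increasing.  Compounds are instances of five category
    exemplars whose QED/SA values and training-set similarity make them fail
    at exactly one stage; the training reference set contains every exemplar
    except the out-of-domain one.  Probabilities are assigned directly
    (0.9-band for predicted actives, 0.1 otherwise) with deterministic
    tie-breaking jitter.

    Returns (records, probabilities, training_records, expected report).
    Raises InfeasiblePlantError if the exemplars' measured properties cannot
    realize the plant (e.g. thresholds moved, or counts increase).
    """
    counts = list(planted_counts)
    if len(counts) != 5:
        raise InfeasiblePlantError("need 5 counts: total + 4 stages")
    if any(b > a for a, b in zip(counts, counts[1:])) or counts[-1] < 0:
        raise InfeasiblePlantError("planted counts must be non-increasing and >= 0")
    n_total, n_act, n_ad, n_qed, n_sa = counts

    from .screenmodel import FingerprintSpec, featurize  # deferred, no cycle

    mols = {k: Chem.MolFromSmiles(s) for k, s in _FUNNEL_EXEMPLARS.items()}
    training_keys = ["pass_all", "fail_sa", "fail_qed", "fail_activity"]
    fps, _ = featurize([mols[k] for k in training_keys] + [mols["fail_ad"]],
                       FingerprintSpec())
    train_fps, ood_fp = fps[:-1], fps[-1]

    # verify the exemplars really realize the plant under default thresholds
    checks = {
        "fail_ad in-domain": max(tanimoto(ood_fp, t) for t in train_fps) < 0.4,
        "fail_qed QED": _QED.qed(mols["fail_qed"]) < 0.7,
        "fail_sa QED": _QED.qed(mols["fail_sa"]) >= 0.7,
        "fail_sa SA": sa_score(mols["fail_sa"]) > 3.0,
        "pass_all QED": _QED.qed(mols["pass_all"]) >= 0.7,
        "pass_all SA": sa_score(mols["pass_all"]) <= 3.0,
        "fail_qed SA": sa_score(mols["fail_qed"]) <= 3.0,
    }
    bad = [k for k, ok in checks.items() if not ok]
    if bad:
        raise InfeasiblePlantError(f"exemplar properties violate the plant: {bad}")

    per_cat = {
        "fail_activity": n_total - n_act,
        "fail_ad": n_act - n_ad,
        "fail_qed": n_ad - n_qed,
        "fail_sa": n_qed - n_sa,
        "pass_all": n_sa,
    }
    records: list[MoleculeRecord] = []
    probs: list[float] = []
    i = 0
    for cat, n_cat in per_cat.items():
        smi = _FUNNEL_EXEMPLARS[cat]
        mol = mols[cat]
        for _ in range(n_cat):
            records.append(
                MoleculeRecord(id=f"cmp{i:05d}", smiles=canonical_smiles(mol),
                               mol=mol, provenance=f"fixtures:funnel:{cat}")
            )
            p = 0.1 if cat == "fail_activity" else 0.9
            probs.append(p - i * 1e-5)  # unique, order-preserving
            i += 1

    training_records = [
        MoleculeRecord(id=f"train{j}", smiles=canonical_smiles(mols[k]),
                       mol=mols[k], provenance="fixtures:funnel:training")
        for j, k in enumerate(training_keys)
    ]
    expected = FunnelReport(
        n_input=n_total,
        stage_order=["activity", "ad", "qed", "sa"],
        survivors=[n_act, n_ad, n_qed, n_sa],
        excluded=[n_total - n_act, n_act - n_ad, n_ad - n_qed, n_qed - n_sa],
        exclusion_pct=[
            100.0 * (a - b) / a if a else 0.0
            for a, b in zip([n_total, n_act, n_ad, n_qed], [n_act, n_ad, n_qed, n_sa])
        ],
    )
    return records, np.array(probs), training_records, expected


# ---------------------------------------------------------------------------
# ranked screens with known enrichment behaviour
# ---------------------------------------------------------------------------

def make_ranked_screen(
    seed: int, N: int, n: int, quality: str | tuple[str, float] = "random"
) -> RankedScreen:
    """Score/label vectors with known expected early-recognition statistics.

    quality:
      * ``"perfect"`` — every active outranks every decoy (BEDROC → 1,
        EF@f = min(1/f, N/n)).
      * ``"worst"`` — every active ranks last (BEDROC → 0, EF@small f = 0).
      * ``"random"`` — scores independent of labels (E[RIE] = E[EF] = 1).
      * ``("exponential", a)`` — active ranks concentrated early with weight
        e^{−a·r/N}, an idealized "good but imperfect" screen.

    Scores follow the docking convention (lower = better).
    """
    if n < 1 or n >= N:
        raise InputError("need 1 <= n < N")
    rng = np.random.default_rng(seed)
    labels = np.zeros(N, dtype=int)

    if isinstance(quality, tuple):
        kind, a = quality
        if kind != "exponential":
            raise InputError(f"unknown quality {quality!r}")
        w = np.exp(-a * (np.arange(N) + 0.5) / N)
        pos = rng.choice(N, size=n, replace=False, p=w / w.sum())
        labels[np.sort(pos)] = 1
        scores = np.arange(N, dtype=float)  # rank position = score
    elif quality == "perfect":
        labels[:n] = 1
        scores = np.arange(N, dtype=float)
    elif quality == "worst":
        labels[N - n:] = 1
        scores = np.arange(N, dtype=float)
    elif quality == "random":
        labels[rng.choice(N, size=n, replace=False)] = 1
        scores = rng.standard_normal(N)
    else:
        raise InputError(f"unknown quality {quality!r}")
    return RankedScreen(scores=scores, labels=labels, lower_is_better=True)


def make_energy_table(
    seed: int, n_frames: int = 800, mean_delta: float = -48.0, sd: float = 4.6,
    er_level: float = -1180.0, el_level: float = -22.0,
) -> pd.DataFrame:
    """Per-frame MM/GBSA energy table (frame, EC, ER, EL) around stated levels.

    EC is constructed as ER + EL + ΔE with ΔE ~ Normal(mean_delta, sd), so the
    aggregate mean/SD are known in expectation.
    """
    rng = np.random.default_rng(seed)
    er = er_level + rng.normal(0, 15.0, n_frames)
    el = el_level + rng.normal(0, 3.0, n_frames)
    delta = rng.normal(mean_delta, sd, n_frames)
    return pd.DataFrame(
        {"frame": np.arange(n_frames), "EC": er + el + delta, "ER": er, "EL": el}
    )
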