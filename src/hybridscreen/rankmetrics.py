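"""Early-recognition statistics, docking-selectivity arithmetic, MM/GBSA aggregation.

A virtual-screening protocol is validated by spiking known actives into a
decoy library, ranking everything by the docking (or model) score, and asking
how early the actives surface.  Beyond plain ROC-AUC this module implements
the exponentially weighted early-recognition pair RIE/BEDROC and the
enrichment factor EF@x%.

Docking scores in kcal/mol are better when more negative; a
``lower_is_better`` flag on RankedScreen governs ranking direction everywhere
(internal ranks are always "best first").  Ties are broken by a stable sort on
(score, index) so BEDROC is deterministic; only the AUC uses midranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemio import InputError
from .screenmodel import roc_auc


@dataclass
class RankedScreen:
    """Scores and binary activity labels for one ranked screen."""

    scores: np.ndarray
    labels: np.ndarray
    lower_is_better: bool = True

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise InputError("scores and labels differ in length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise InputError("labels must be binary")
        if self.n_actives < 1:
            raise InputError("a ranked screen needs at least one active")
        if self.n_actives >= self.N:
            raise InputError("a ranked screen needs at least one inactive")

    @property
    def N(self) -> int:
        return int(self.scores.size)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def Ra(self) -> float:
        return self.n_actives / self.N

    def active_ranks(self) -> np.ndarray:
        """1-based ranks of the actives, best score first; stable in input order."""
        key = self.scores if self.lower_is_better else -self.scores
        order = np.argsort(key, kind="stable")
        ranks = np.empty(self.N, dtype=int)
        ranks[order] = np.arange(1, self.N + 1)
        return np.sort(ranks[self.labels == 1])


@dataclass(frozen=True)
class EnrichmentSpec:
    alpha: float = 160.9
    ef_fractions: tuple[float, ...] = (0.02, 0.05)

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if any(not 0 < f <= 1 for f in self.ef_fractions):
            raise ValueError("EF fractions must be in (0, 1]")


# ---------------------------------------------------------------------------
# early-recognition metrics
# ---------------------------------------------------------------------------

def rie(screen: RankedScreen, alpha: float) -> float:
    """Robust initial enhancement at exponential weight ``alpha``.

    RIE = (1/n)·Σ_actives e^{−α·rᵢ/N}  ÷  [(1/N)·(1−e^{−α})/(e^{α/N}−1)],
    i.e. the exponentially weighted mean of the active ranks relative to its
    expectation under a uniform spread.  RIE → 1 for a random ranking and for
    α → 0⁺ regardless of ranking.
    """
    if alpha <= 0:
        raise InputError("alpha must be positive")
    ranks = screen.active_ranks()
    N, n = screen.N, screen.n_actives
    observed = np.exp(-alpha * ranks / N).sum() / n
    expected = (1.0 / N) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)
    return float(observed / expected)


def bedroc(screen: RankedScreen, alpha: float) -> float:
    """Boltzmann-enhanced discrimination of ROC: RIE rescaled into [0, 1].

    BEDROC = RIE·Ra·sinh(α/2) / (cosh(α/2) − cosh(α/2 − α·Ra))
             + 1 / (1 − e^{α(1−Ra)}).
    """
    Ra = screen.Ra
    a = alpha
    scale = Ra * math.sinh(a / 2) / (math.cosh(a / 2) - math.cosh(a / 2 - a * Ra))
    offset = 1.0 / (1.0 - math.exp(a * (1.0 - Ra)))
    val = rie(screen, a) * scale + offset
    # the rescaling is in [0,1] by construction; clip floating-point spill
    return float(min(1.0, max(0.0, val)))


def enrichment_factor(screen: RankedScreen, fraction: float) -> float:
    """EF@fraction: active rate in the top ceil(fraction·N) over the base rate."""
    if not 0 < fraction <= 1:
        raise InputError("fraction must be in (0, 1]")
    N, n = screen.N, screen.n_actives
    k = math.ceil(fraction * N)
    hits = int((screen.active_ranks() <= k).sum())
    return float((hits / k) / (n / N))


def roc_auc_screen(screen: RankedScreen) -> float:
    """Rank-statistic ROC-AUC (midrank ties), on the "higher is better" scale."""
    goodness = -screen.scores if screen.lower_is_better else screen.scores
    return roc_auc(goodness, screen.labels)


def accumulation_curve(screen: RankedScreen) -> pd.DataFrame:
    """Fraction of actives recovered vs fraction of library screened (CSV-ready)."""
    ranks = screen.active_ranks()
    N, n = screen.N, screen.n_actives
    found = np.cumsum(np.isin(np.arange(1, N + 1), ranks))
    return pd.DataFrame(
        {"fraction_screened": np.arange(1, N + 1) / N, "fraction_found": found / n}
    )


def enrichment_report(screen: RankedScreen, spec: EnrichmentSpec) -> dict:
    """All validation statistics for one ranked screen as a JSON-ready dict."""
    return {
        "N": screen.N,
        "n_actives": screen.n_actives,
        "roc_auc": roc_auc_screen(screen),
        "alpha": spec.alpha,
        "rie": rie(screen, spec.alpha),
        "bedroc": bedroc(screen, spec.alpha),
        "enrichment_factors": {
            f"EF@{f:g}": enrichment_factor(screen, f) for f in spec.ef_fractions
        },
    }


# ---------------------------------------------------------------------------
# docking selectivity
# ---------------------------------------------------------------------------

@dataclass
class DockScorePair:
    """XP docking scores of one compound against the two domains.

    Scores are negative-better; ``gap = score_jh1 − score_jh2`` is positive
    when the compound prefers the regulatory (JH2) pocket.
    """

    compound_id: str
    score_jh2: Optional[float]
    score_jh1: Optional[float]

    @property
    def gap(self) -> Optional[float]:
        if self.score_jh1 is None or self.score_jh2 is None:
            return None
        return self.score_jh1 - self.score_jh2


def selectivity_gap(pairs: Sequence[DockScorePair]) -> pd.DataFrame:
    """Selectivity table sorted by gap descending; incomplete rows flagged."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "compound_id": p.compound_id,
                "score_jh2": p.score_jh2,
                "score_jh1": p.score_jh1,
                "gap": p.gap,
                "missing_score": p.gap is None,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["missing_score", "gap"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# MM/GBSA aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyRecord:
    """Per-frame total energies (kcal/mol) of complex, receptor and ligand."""

    ec: float
    er: float
    el: float

    @property
    def delta_e(self) -> float:
        """Binding energy ΔE = EC − (ER + EL); more negative = stronger."""
        return self.ec - (self.er + self.el)


def mmgbsa_aggregate(frames: Sequence[EnergyRecord]) -> tuple[float, float, int]:
    """Ensemble mean ± sample SD (n−1) of per-frame ΔE = EC − (ER + EL).

    A single frame is allowed (SD reported as 0.0); an empty ensemble is an
    error.
    """
    if len(frames) == 0:
        raise InputError("mmgbsa_aggregate: no frames")
    deltas = np.array([f.delta_e for f in frames], dtype=float)
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0
    return mean, sd, len(deltas)


def mmgbsa_from_table(df: pd.DataFrame) -> tuple[float, float, int]:
    """Aggregate a per-frame energy table with columns EC, ER, EL."""
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("ec", "er", "el") if c not in cols]
    if missing:
        raise InputError(f"energy table missing columns: {missing}")
    frames = [
        EnergyRecord(float(r[cols["ec"]]), float(r[cols["er"]]), float(r[cols["el"]]))
        for _, r in df.iterrows()
    ]
    return mmgbsa_aggregate(frames)
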