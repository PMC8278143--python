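"""Conventional radiobiology endpoints: clonogenic survival and death gating.

Colony-forming assay (CFA): the plating efficiency PE of a sample is the
fraction of seeded cells that founded a colony of at least 50 cells; the
survival fraction SF divides the sample PE by the mean control PE, with
Gaussian error propagation

    dSF = SF * sqrt((dPE/PE)^2 + (dPE0/PE0)^2).

Dose response follows the linear-quadratic model

    SF(D) = exp(-(alpha*D + beta*D^2)),

fitted by weighted least squares in log space (which linearises the model
exactly in alpha and beta).

Caspase3/7-Sytox gating classifies each cell by its two stain calls:
Caspase+/Sytox+ late apoptotic, Caspase+/Sytox- early apoptotic,
Caspase-/Sytox+ necrotic, Caspase-/Sytox- vital; dead cells are the late
apoptotic plus necrotic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ColonyRecord",
    "SurvivalRecord",
    "survival_fraction",
    "sf_uncertainty",
    "LQModel",
    "lq_evaluate",
    "lq_fit",
    "GatingTable",
    "GateSummary",
    "gate_fractions",
    "GATE_CATEGORIES",
]


@dataclass(frozen=True)
class ColonyRecord:
    """One well of a colony-forming assay.

    ``colonies_ge50`` counts only colonies with at least 50 cells; enforcing
    that size cut is a data-entry contract of the assay, not a computation.
    """

    sample_id: str
    dose_gy: float
    seeded_cells: int
    colonies_ge50: int

    def __post_init__(self) -> None:
        if self.seeded_cells <= 0:
            raise ValueError("seeded_cells must be > 0")
        if not (0 <= self.colonies_ge50 <= self.seeded_cells):
            raise ValueError("need 0 <= colonies_ge50 <= seeded_cells")

    @property
    def pe(self) -> float:
        return self.colonies_ge50 / self.seeded_cells


@dataclass
class SurvivalRecord:
    """Survival fraction of one sample against the unirradiated controls."""

    sample_id: str
    dose_gy: float
    pe: float
    dpe: float
    pe0_mean: float
    dpe0: float
    sf: float
    dsf: float


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def sf_uncertainty(sf: float, pe: float, dpe: float, pe0: float, dpe0: float) -> float:
    """Gaussian propagation of the PE and control-PE errors into SF."""
    return sf * float(np.hypot(dpe / pe, dpe0 / pe0))


def survival_fraction(
    record: Union[ColonyRecord, Sequence[ColonyRecord]],
    controls: Sequence[ColonyRecord],
) -> SurvivalRecord:
    """SF of a sample (one well or replicate wells) against control wells.

    The control uncertainty is the SEM over the control wells (at least two
    are required).  The sample uncertainty is the SEM over replicate wells
    when replicates are given, else the binomial approximation
    sqrt(PE*(1-PE)/seeded) for a single well.
    """
    if len(controls) < 2:
        raise ValueError(
            "need >= 2 control wells: the control uncertainty is the SEM, "
            "which is undefined for a single well"
        )
    pe0_values = np.array([c.pe for c in controls], dtype=float)
    pe0_mean = float(pe0_values.mean())
    if pe0_mean == 0:
        raise ValueError("mean control plating efficiency is zero")
    dpe0 = _sem(pe0_values)

    records = [record] if isinstance(record, ColonyRecord) else list(record)
    if not records:
        raise ValueError("no sample wells given")
    pes = np.array([r.pe for r in records], dtype=float)
    pe = float(pes.mean())
    if pe == 0:
        raise ValueError("sample plating efficiency is zero")
    if len(records) > 1:
        dpe = _sem(pes)
    else:
        dpe = float(np.sqrt(pe * (1.0 - pe) / records[0].seeded_cells))
    sf = pe / pe0_mean
    dsf = sf_uncertainty(sf, pe, dpe, pe0_mean, dpe0)
    return SurvivalRecord(
        sample_id=records[0].sample_id,
        dose_gy=records[0].dose_gy,
        pe=pe,
        dpe=dpe,
        pe0_mean=pe0_mean,
        dpe0=dpe0,
        sf=sf,
        dsf=dsf,
    )


# ---------------------------------------------------------------------------
# Linear-quadratic model


@dataclass
class LQModel:
    """Linear-quadratic dose response: SF(D) = exp(-(alpha*D + beta*D^2))."""

    alpha: float  # 1/Gy
    beta: float  # 1/Gy^2
    alpha_sigma: float = 0.0
    beta_sigma: float = 0.0
    cov: Optional[np.ndarray] = None  # 2x2 (alpha, beta) covariance


def lq_evaluate(model: LQModel, dose_gy: float) -> tuple[float, float]:
    """Closed-form SF at a dose, with linearly propagated uncertainty.

    The alpha/beta errors are treated as independent unless the model
    carries a covariance matrix.
    """
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    D = float(dose_gy)
    sf = float(np.exp(-(model.alpha * D + model.beta * D * D)))
    grad = np.array([-D * sf, -D * D * sf])
    if model.cov is not None:
        var = float(grad @ np.asarray(model.cov) @ grad)
    else:
        var = float((grad[0] * model.alpha_sigma) ** 2 + (grad[1] * model.beta_sigma) ** 2)
    return sf, float(np.sqrt(max(var, 0.0)))


def lq_fit(points: Sequence[tuple[float, float, float]]) -> LQModel:
    """Weighted least-squares LQ fit of (dose, SF, sigma_SF) points.

    The fit runs on ln SF, which is exactly linear in alpha and beta;
    weights transform as sigma_lnSF = sigma_SF / SF.  Non-negativity of the
    coefficients is not enforced, so a slightly negative beta can emerge
    from noisy data.  At least three distinct doses are required.
    """
    pts = [(float(d), float(sf), float(s)) for d, sf, s in points]
    if any(sf <= 0 for _, sf, _ in pts):
        raise ValueError("all SF values must be > 0 for the log-space fit")
    if len({d for d, _, _ in pts}) < 3:
        raise ValueError("need >= 3 distinct doses")
    D = np.array([p[0] for p in pts])
    y = np.log([p[1] for p in pts])
    s_sf = np.array([p[2] for p in pts])
    sf = np.array([p[1] for p in pts])
    sigma = np.where(s_sf > 0, s_sf / sf, 1.0)  # unweighted rows where sigma unknown
    X = np.column_stack([-D, -(D**2)])
    w = 1.0 / sigma
    Xw = X * w[:, None]
    yw = y * w
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    cov = np.linalg.inv(Xw.T @ Xw)
    return LQModel(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        alpha_sigma=float(np.sqrt(cov[0, 0])),
        beta_sigma=float(np.sqrt(cov[1, 1])),
        cov=cov,
    )


# ---------------------------------------------------------------------------
# Caspase3/7-Sytox gating

#: Category order: (Caspase, Sytox) call -> biological category.
GATE_CATEGORIES = {
    "caspase_pos_sytox_pos": "late_apoptotic",
    "caspase_pos_sytox_neg": "early_apoptotic",
    "caspase_neg_sytox_pos": "necrotic",
    "caspase_neg_sytox_neg": "vital",
}


@dataclass
class GatingTable:
    """Per-sample counts of the four Caspase3/7 x Sytox gates.

    ``counts`` is a DataFrame indexed by sample id with the four count
    columns named in :data:`GATE_CATEGORIES`.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(GATE_CATEGORIES) - set(self.counts.columns)
        if missing:
            raise ValueError(f"gating table missing columns {sorted(missing)}")
        if (self.counts[list(GATE_CATEGORIES)] < 0).to_numpy().any():
            raise ValueError("gate counts must be >= 0")
        totals = self.counts[list(GATE_CATEGORIES)].sum(axis=1)
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(f"all-zero gating sample(s): {list(zero.index)}")


@dataclass
class GateSummary:
    """Gate fractions per sample with across-sample mean and SEM."""

    fractions: pd.DataFrame  # per sample, columns = biological categories
    mean: pd.Series
    sem: pd.Series
    dead_fraction: float  # late apoptotic + necrotic, mean over samples
    early_apoptotic_share: float  # early / (early + late)
    late_apoptotic_share: float


def gate_fractions(table: GatingTable) -> GateSummary:
    """Fractions of the four gated categories, mean +/- SEM across samples.

    Also derives the dead fraction (late apoptotic + necrotic) and the
    shares of early and late apoptosis among all apoptotic cells.
    """
    counts = table.counts[list(GATE_CATEGORIES)]
    totals = counts.sum(axis=1)
    fractions = counts.div(totals, axis=0)
    fractions.columns = [GATE_CATEGORIES[c] for c in fractions.columns]
    mean = fractions.mean(axis=0)
    n = len(fractions)
    sem = fractions.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else fractions.iloc[0] * np.nan
    apoptotic = mean["early_apoptotic"] + mean["late_apoptotic"]
    if apoptotic > 0:
        early_share = float(mean["early_apoptotic"] / apoptotic)
        late_share = float(mean["late_apoptotic"] / apoptotic)
    else:
        early_share = late_share = float("nan")
    return GateSummary(
        fractions=fractions,
        mean=mean,
        sem=sem,
        dead_fraction=float(mean["late_apoptotic"] + mean["necrotic"]),
        early_apoptotic_share=early_share,
        late_apoptotic_share=late_share,
    )
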