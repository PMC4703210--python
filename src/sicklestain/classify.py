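"""Genotype calls from stain indices and %HbS calibration.

The S-index rises with the HbS fraction, so two cutoffs partition it into
three bands: AA (no HbS), AS (trait) and SS (disease).  Boundary values
resolve to the less severe genotype — a deterministic, conservative rule for
a screening test.  Cutoffs are fitted from labelled data by maximizing
Youden's J over candidate midpoints, because the assay defines no universal
numeric cutoffs (they depend on paper, buffer and scanner); a config file
can pin fitted values for reproducibility.

HbSC disease cannot be separated from trait by S-index alone (similar %HbS);
the C-index adds total hemoglobin, which is typically lower in HbSC, so
calls *below* the C-index cutoff refine an AS-band call to SC.

A linear calibration maps S-index to %HbS (ordinary least squares on
dilution-series data where %HbS is known by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, FittingError
from .genotypes import Genotype


@dataclass(frozen=True)
class Thresholds:
    """S-index cutoffs (and optional C-index cutoff) for genotype calls.

    ``tau_any_s`` separates AA from {AS, SS}; ``tau_ss`` separates AS from
    SS; ``c_cutoff`` separates SC (below) from AS (at or above).
    """

    tau_any_s: float
    tau_ss: float
    c_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not (self.tau_any_s > 0 and self.tau_ss > 0):
            raise DomainError("cutoffs must be positive")
        if not self.tau_any_s < self.tau_ss:
            raise DomainError("require tau_any_s < tau_ss")
        if self.c_cutoff is not None and self.c_cutoff <= 0:
            raise DomainError("c_cutoff must be positive")


@dataclass(frozen=True)
class GenotypeCall:
    """One classification outcome with the score that produced it."""

    label: Genotype
    score_used: float
    extended_label: Genotype | None = None


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from S-index to %HbS: ``percent = slope * s + intercept``."""

    slope: float
    intercept: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise DomainError("residual_sd must be non-negative")


def classify_s_index(s: float, thresholds: Thresholds) -> GenotypeCall:
    """Three-band genotype call from an S-index value.

    ``s <= tau_any_s`` -> AA; ``tau_any_s < s <= tau_ss`` -> AS; above -> SS.
    """
    if not math.isfinite(s):
        raise DomainError("S-index must be finite")
    if s < 0:
        raise DomainError("S-index must be non-negative")
    if s <= thresholds.tau_any_s:
        label = Genotype.AA
    elif s <= thresholds.tau_ss:
        label = Genotype.AS
    else:
        label = Genotype.SS
    return GenotypeCall(label=label, score_used=s)


def classify_c_index(c: float, c_cutoff: float) -> GenotypeCall:
    """Refine an AS-band call into AS vs SC using the C-index.

    HbSC samples carry less total hemoglobin, so a normalized value
    ``c / c_cutoff < 1`` calls SC; the boundary resolves to AS.
    """
    if c_cutoff <= 0:
        raise DomainError("c_cutoff must be positive")
    if not math.isfinite(c) or c < 0:
        raise DomainError("C-index must be finite and non-negative")
    normalized = c / c_cutoff
    extended = Genotype.SC if normalized < 1.0 else Genotype.AS
    return GenotypeCall(label=Genotype.AS, score_used=normalized, extended_label=extended)


def _youden_cutoff(scores: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    """Cutoff (positive = score > cutoff) maximizing J = sens + spec - 1.

    Candidates are midpoints between adjacent distinct sorted scores; ties in
    J break toward higher specificity, then toward the higher cutoff.
    Returns (cutoff, best_J).
    """
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise FittingError("need at least two distinct scores to place a cutoff")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise FittingError("both classes must be present to fit a cutoff")
    best: tuple[float, float, float] | None = None  # (J, spec, cutoff)
    for c in candidates:
        called = scores > c
        sens = float((called & positive).sum()) / n_pos
        spec = float((~called & ~positive).sum()) / n_neg
        j = sens + spec - 1.0
        key = (j, spec, c)
        if best is None or key > best:
            best = key
    assert best is not None
    return float(best[2]), float(best[0])


def fit_thresholds(
    scores: Sequence[float], labels: Sequence[Genotype | str]
) -> Thresholds:
    """Fit the two S-index cutoffs from labelled scores.

    ``tau_any_s`` maximizes Youden's J for AA vs {AS, SS}; ``tau_ss`` for SS
    vs {AA, AS}.  Requires at least two genotype classes; with no SS present
    ``tau_ss`` is placed above the maximum observed score so nothing is
    called SS (and symmetrically for a missing AA class).
    """
    s = np.asarray(scores, dtype=np.float64)
    labs = [Genotype(l) for l in labels]
    if s.size != len(labs):
        raise DomainError("scores and labels must have equal length")
    if len(set(labs)) < 2:
        raise FittingError("threshold fitting needs at least two classes")
    is_aa = np.array([l is Genotype.AA for l in labs])
    is_ss = np.array([l is Genotype.SS for l in labs])

    if is_aa.any():
        tau_any, _ = _youden_cutoff(s, ~is_aa)
    else:
        tau_any = float(s.min()) / 2.0 if s.min() > 0 else 1e-9
    if is_ss.any():
        tau_ss, _ = _youden_cutoff(s, is_ss)
    else:
        tau_ss = float(s.max()) + 1.0
    if tau_any == tau_ss:
        # two-class AA/SS data: both binary splits pick the same cutoff, so
        # the trait band collapses to zero width
        tau_ss = float(np.nextafter(tau_ss, np.inf))
    if not tau_any < tau_ss:
        raise FittingError(
            f"fitted cutoffs are not ordered (tau_any_s={tau_any:.3g} >= tau_ss={tau_ss:.3g}); "
            "the score does not separate the classes in the expected order"
        )
    return Thresholds(tau_any_s=tau_any, tau_ss=tau_ss)


def fit_c_cutoff_full_sensitivity(
    c_values: Sequence[float], is_sc: Sequence[bool]
) -> float:
    """Smallest C-index cutoff that flags every SC sample (100% sensitivity).

    SC calls are ``c < cutoff``, so the cutoff sits just above the largest
    SC C-index (at the next observed non-SC value, or that maximum plus a
    relative epsilon when none lies above).
    """
    c = np.asarray(c_values, dtype=np.float64)
    sc = np.asarray(is_sc, dtype=bool)
    if c.size != sc.size or c.size == 0:
        raise DomainError("c_values and is_sc must be equal-length and non-empty")
    if not sc.any():
        raise FittingError("no SC samples to set the cutoff from")
    max_sc = float(c[sc].max())
    above = c[c > max_sc]
    return float(above.min()) if above.size else max_sc * (1.0 + 1e-9)


def fit_hbs_calibration(
    pairs: Sequence[tuple[float, float]]
) -> CalibrationModel:
    """Ordinary least squares of true %HbS on measured S-index.

    ``residual_sd`` is the sample SD (ddof=1) of predicted minus true %HbS
    over the fitting set.  Requires >= 3 pairs with >= 2 distinct S-index
    values.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DomainError("need at least 3 (s_index, percent_hbs) pairs")
    s, y = arr[:, 0], arr[:, 1]
    if np.unique(s).size < 2:
        raise FittingError("all S-index values identical; calibration is degenerate")
    slope, intercept = np.polyfit(s, y, 1)
    pred = slope * s + intercept
    residual_sd = float(np.std(pred - y, ddof=1))
    return CalibrationModel(slope=float(slope), intercept=float(intercept), residual_sd=residual_sd)


def predict_percent_hbs(model: CalibrationModel, s: float) -> float:
    """Predicted %HbS for an S-index value, clamped to [0, 100]."""
    if not math.isfinite(s):
        raise DomainError("S-index must be finite")
    return float(np.clip(model.slope * s + model.intercept, 0.0, 100.0))


__all__ = [
    "Thresholds",
    "GenotypeCall",
    "CalibrationModel",
    "classify_s_index",
    "classify_c_index",
    "fit_thresholds",
    "fit_c_cutoff_full_sensitivity",
    "fit_hbs_calibration",
    "predict_percent_hbs",
]
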