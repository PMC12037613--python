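"""Probit-based relative biopotency of enzyme-inhibition assays.

The assay design: a reference preparation and test batches are each run
as a geometric dilution series (default four doses at a 1:0.5 ratio),
each dose read in replicate on a fluorescence plate.  Readings become
inhibition fractions against the plate's enzyme-control and blank wells,
inhibitions become probability units (probits, Phi^{-1}(p) + 5), and a
straight line of probit against log10 dose is fitted per preparation by
ordinary least squares on the per-dose mean inhibition — the classical
"simple" probability-unit method.

Relative potency comes from the parallel-line model: with a common slope
b fitted to both lines,

    M = (xbar_ref - xbar_test) + (ybar_test - ybar_ref) / b

is the log10 potency ratio, R = 10^M, and the batch potency is
R x reference_potency (e.g. 1000 U/ug for the safflower S1 reference, or
100 U/mg when celecoxib anchors the plate).  Confidence limits for M use
Fieller's theorem with the pooled residual variance; FL% is the half-width
of the potency interval relative to the estimate.  A parallelism t-test of
the two separate slopes guards the model assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError, ValidationError

log = logging.getLogger("tcqe")


def design_dilution_series(
    top_dose: float, n_dilutions: int = 4, ratio: float = 0.5
) -> list[float]:
    """Descending geometric dose series [top, top*ratio, top*ratio^2, ...]."""
    if top_dose <= 0:
        raise ValidationError(f"top_dose must be positive, got {top_dose}")
    if not 0 < ratio < 1:
        raise ValidationError(f"ratio must lie in (0, 1), got {ratio}")
    if n_dilutions < 3:
        raise ValidationError(f"need >= 3 dilutions, got {n_dilutions}")
    return [top_dose * ratio**i for i in range(n_dilutions)]


def inhibition_from_readings(
    sample_signal: float, enzyme_control: float, blank: float
) -> float:
    """Inhibition fraction from raw plate signals, clipped to [0, 1].

    inhibition = 1 - (sample - blank) / (control - blank).
    """
    if enzyme_control <= blank:
        raise AssayError(
            f"assay invalid: enzyme control ({enzyme_control}) must exceed "
            f"blank ({blank})"
        )
    raw = 1.0 - (sample_signal - blank) / (enzyme_control - blank)
    clipped = min(1.0, max(0.0, raw))
    if clipped != raw:
        log.debug("inhibition clipped from %g to %g", raw, clipped)
    return clipped


def probit_transform(p: float | np.ndarray) -> float | np.ndarray:
    """Classical probability units: probit(p) = Phi^{-1}(p) + 5."""
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValidationError(f"probability outside [0, 1]: {p}")
    out = stats.norm.ppf(p_arr) + 5.0
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


def adjust_boundary(p: float, n_replicates: int) -> float:
    """Move an inhibition of exactly 0 or 1 off the boundary.

    0 -> 1/(4r) and 1 -> 1 - 1/(4r), the standard continuity adjustment
    for empirical probits with r replicate readings.
    """
    if p <= 0.0:
        return 1.0 / (4.0 * n_replicates)
    if p >= 1.0:
        return 1.0 - 1.0 / (4.0 * n_replicates)
    return p


@dataclass
class DoseResponseSeries:
    """Mean inhibition per dose for one preparation."""

    batch: str
    doses: np.ndarray            # strictly positive, any order
    inhibitions: np.ndarray      # per-dose mean inhibition, in [0, 1]
    n_replicates: int = 1
    role: str = "test"           # "reference" or "test"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.inhibitions = np.asarray(self.inhibitions, dtype=float)
        if len(np.unique(self.doses)) < 3:
            raise ValidationError(
                f"batch {self.batch}: need >= 3 distinct doses, got "
                f"{len(np.unique(self.doses))}"
            )
        if (self.doses <= 0).any():
            raise ValidationError(f"batch {self.batch}: doses must be positive")
        if ((self.inhibitions < 0) | (self.inhibitions > 1)).any():
            raise ValidationError(
                f"batch {self.batch}: inhibitions must lie in [0, 1]"
            )

    def usable_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(log10 dose, probit) pairs after boundary adjustment."""
        x, y = [], []
        for d, p in zip(self.doses, self.inhibitions):
            p_adj = adjust_boundary(p, self.n_replicates)
            if 0.0 < p_adj < 1.0:
                x.append(math.log10(d))
                y.append(probit_transform(p_adj))
        return np.asarray(x), np.asarray(y)


@dataclass
class ProbitLine:
    batch: str
    intercept: float
    slope: float                 # probit units per log10 dose
    residual_variance: float
    n_points: int
    dose_range: tuple[float, float]
    x: np.ndarray = field(repr=False, default=None)   # log10 doses used
    y: np.ndarray = field(repr=False, default=None)   # probits used

    @property
    def ed50(self) -> float:
        """Dose giving probit 5 (50% inhibition)."""
        return 10.0 ** ((5.0 - self.intercept) / self.slope)


def fit_probit_line(series: DoseResponseSeries) -> ProbitLine:
    """Unweighted OLS of probit(mean inhibition) on log10(dose)."""
    x, y = series.usable_points()
    if len(x) < 3:
        raise ValidationError(
            f"batch {series.batch}: only {len(x)} usable point(s); "
            "need >= 3 inhibitions strictly inside (0, 1)"
        )
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    df = len(x) - 2
    s2 = float(resid @ resid / df) if df > 0 else 0.0
    if slope <= 0:
        log.warning("batch %s: non-ascending dose response (slope %.3g)",
                    series.batch, slope)
    return ProbitLine(
        batch=series.batch,
        intercept=float(intercept),
        slope=float(slope),
        residual_variance=s2,
        n_points=len(x),
        dose_range=(float(series.doses.min()), float(series.doses.max())),
        x=x,
        y=y,
    )


@dataclass
class PotencyEstimate:
    batch: str
    log_ratio: float             # M, log10 potency ratio vs reference
    relative_potency: float      # R = 10^M
    potency: float               # R x reference_potency
    potency_low: float
    potency_high: float
    fl_percent: float            # half-width / estimate x 100
    parallelism_p: float
    g: float                     # Fieller g statistic
    confidence_level: float = 0.95


def _as_line(obj) -> ProbitLine:
    if isinstance(obj, ProbitLine):
        return obj
    if isinstance(obj, DoseResponseSeries):
        return fit_probit_line(obj)
    raise ValidationError(f"expected ProbitLine or DoseResponseSeries, got {type(obj)}")


def parallelism_check(test, reference) -> tuple[float, bool]:
    """t-test of slope equality between the two probit lines.

    Returns (p_value, flag) with flag True when p < 0.05, i.e. evidence
    of non-parallelism.
    """
    lt, lr = _as_line(test), _as_line(reference)
    sxx_t = float(np.sum((lt.x - lt.x.mean()) ** 2))
    sxx_r = float(np.sum((lr.x - lr.x.mean()) ** 2))
    df = (lt.n_points - 2) + (lr.n_points - 2)
    if df <= 0:
        return 1.0, False
    s2 = (
        lt.residual_variance * (lt.n_points - 2)
        + lr.residual_variance * (lr.n_points - 2)
    ) / df
    se = math.sqrt(s2 * (1.0 / sxx_t + 1.0 / sxx_r))
    if se == 0:
        p = 1.0 if lt.slope == lr.slope else 0.0
    else:
        t = (lt.slope - lr.slope) / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(p), bool(p < 0.05)


def estimate_potency(
    test,
    reference,
    reference_potency: float = 1000.0,
    confidence_level: float = 0.95,
) -> PotencyEstimate:
    """Parallel-line relative potency of ``test`` against ``reference``.

    A common slope b is fitted to both lines (pooled least squares with
    separate intercepts); the log10 potency ratio is
    M = (xbar_ref - xbar_test) + (ybar_test - ybar_ref)/b; Fieller's
    theorem gives the fiducial limits using the pooled residual variance
    with n_test + n_ref - 3 degrees of freedom.  g >= 1 (slope not
    significantly nonzero at the chosen level) invalidates the assay.
    """
    lt, lr = _as_line(test), _as_line(reference)
    par_p, _ = parallelism_check(lt, lr)

    xt, yt, xr, yr = lt.x, lt.y, lr.x, lr.y
    nt, nr = len(xt), len(xr)
    xbar_t, ybar_t = float(xt.mean()), float(yt.mean())
    xbar_r, ybar_r = float(xr.mean()), float(yr.mean())
    sxx = float(np.sum((xt - xbar_t) ** 2) + np.sum((xr - xbar_r) ** 2))
    sxy = float(
        np.sum((xt - xbar_t) * (yt - ybar_t)) + np.sum((xr - xbar_r) * (yr - ybar_r))
    )
    if sxx == 0:
        raise AssayError("assay invalid: no dose spread")
    b = sxy / sxx
    if b == 0:
        raise AssayError("assay invalid: zero common slope")
    # pooled residual SS about the two parallel lines
    resid_t = (yt - ybar_t) - b * (xt - xbar_t)
    resid_r = (yr - ybar_r) - b * (xr - xbar_r)
    df = nt + nr - 3
    if df <= 0:
        raise AssayError("assay invalid: no residual degrees of freedom")
    s2 = float(resid_t @ resid_t + resid_r @ resid_r) / df

    m_prime = (ybar_t - ybar_r) / b          # horizontal offset component
    m_hat = (xbar_r - xbar_t) + m_prime
    tcrit = stats.t.ppf(0.5 + confidence_level / 2.0, df)
    g = tcrit**2 * s2 / (b**2 * sxx)
    if g >= 1.0:
        raise AssayError(
            "assay invalid: unbounded fiducial interval "
            f"(g = {g:.3f} >= 1; slope not significantly nonzero)"
        )
    half = (
        tcrit
        * math.sqrt(s2)
        / abs(b)
        * math.sqrt((1.0 - g) * (1.0 / nt + 1.0 / nr) + m_prime**2 / sxx)
    )
    m_low = (xbar_r - xbar_t) + (m_prime - half) / (1.0 - g)
    m_high = (xbar_r - xbar_t) + (m_prime + half) / (1.0 - g)

    potency = 10.0**m_hat * reference_potency
    low = 10.0**m_low * reference_potency
    high = 10.0**m_high * reference_potency
    fl = (high - low) / (2.0 * potency) * 100.0
    return PotencyEstimate(
        batch=lt.batch,
        log_ratio=m_hat,
        relative_potency=10.0**m_hat,
        potency=potency,
        potency_low=low,
        potency_high=high,
        fl_percent=fl,
        parallelism_p=par_p,
        g=g,
        confidence_level=confidence_level,
    )


def validation_rsd(potency_replicates) -> dict[str, float]:
    """Relative standard deviation of replicate potency determinations.

    Used for the method-validation figures of merit (precision,
    repeatability, stability), each reported as RSD% with its n.
    """
    values = np.asarray(list(potency_replicates), dtype=float)
    if len(values) < 2:
        raise ValidationError(f"need >= 2 replicates, got {len(values)}")
    mean = float(values.mean())
    if mean <= 0:
        raise ValidationError(f"replicate mean must be positive, got {mean}")
    sd = float(values.std(ddof=1))
    return {"rsd_percent": sd / mean * 100.0, "n": len(values), "mean": mean}


def series_from_plate(
    plate: pd.DataFrame, batch: str, role: str = "test"
) -> DoseResponseSeries:
    """Build a dose-response series for one batch from a long plate table.

    ``plate`` columns: batch, dose, replicate, signal, well_role in
    {sample, control, blank}.  Control and blank wells are shared across
    batches (their batch field is ignored); replicate sample signals are
    converted to inhibition individually and averaged per dose.
    """
    controls = plate.loc[plate["well_role"] == "control", "signal"].astype(float)
    blanks = plate.loc[plate["well_role"] == "blank", "signal"].astype(float)
    if controls.empty or blanks.empty:
        raise AssayError("plate lacks control or blank wells")
    control, blank = float(controls.mean()), float(blanks.mean())
    rows = plate[(plate["batch"] == batch) & (plate["well_role"] == "sample")]
    if rows.empty:
        raise ValidationError(f"no sample wells for batch {batch!r}")
    doses, means, n_rep = [], [], 0
    for dose, grp in rows.groupby("dose"):
        inh = [
            inhibition_from_readings(float(s), control, blank)
            for s in grp["signal"]
        ]
        doses.append(float(dose))
        means.append(float(np.mean(inh)))
        n_rep = max(n_rep, len(inh))
    return DoseResponseSeries(
        batch=batch,
        doses=np.asarray(doses),
        inhibitions=np.asarray(means),
        n_replicates=n_rep,
        role=role,
    )
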