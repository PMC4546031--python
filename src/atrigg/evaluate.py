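"""Agreement, precision and diagnostic statistics for the IgG assay.

Covers everything used to judge the calibration: the RMSE family (RMSEC on
the calibration set, RMSEP on the prediction set), Pearson r, Lin's
concordance correlation coefficient (CCC), Bland–Altman limits of
agreement, the small-sample-corrected coefficient of variation
CV* = CV (1 + 1/(4n)), the ratio of predictive deviation RPD = SD/RMSEP and
range error ratio RER = range/RMSEP with their conventional interpretation
bands, and 2x2 diagnostic characteristics for failure of transfer of
passive immunity (FTPI, serum IgG < 1000 mg/dL).

Conventions: Bland–Altman differences are test - reference with 1.96-sigma
limits from the sample SD; CCC uses population (1/n) moments per Lin's
definition; the RPD numerator is the population SD of the reference values
(the sample SD is reported alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = [
    "AgreementReport",
    "DiagnosticTable",
    "PrecisionRecord",
    "rmse",
    "pearson",
    "concordance_ccc",
    "bland_altman",
    "cv_star",
    "rpd_rer",
    "classify_ftpi",
    "diagnostic_table",
    "evaluate_agreement",
    "FTPI_CUTOFF",
]

FTPI_CUTOFF = 1000.0  # mg/dL

RPD_POOR = "poor"
RPD_SCREENING = "screening"
RPD_QUANTIFICATION = "quantification"
RPD_ACCURATE = "accurate quantification"


def _paired(a, b, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < min_len:
        raise ValueError(f"need at least {min_len} pairs")
    return a, b


def rmse(reference, predicted) -> float:
    """Root mean squared difference, mg/dL."""
    r, p = _paired(reference, predicted, min_len=1)
    return float(np.sqrt(np.mean((p - r) ** 2)))


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _paired(x, y, min_len=2)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def concordance_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with population (1/n)
    moments; penalizes both dispersion and location shift, so |CCC| <= |r|.
    """
    x, y = _paired(x, y, min_len=2)
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("CCC undefined when both inputs are the same constant")
    return float(2.0 * sxy / denom)


def bland_altman(reference, test) -> tuple[float, float, float]:
    """Bland–Altman agreement: mean difference and 95% limits of agreement.

    Differences are test - reference; limits are mean +/- 1.96 x sample SD.
    Returns (mean_diff, loa_low, loa_high) in mg/dL.
    """
    r, t = _paired(reference, test, min_len=2)
    d = t - r
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


@dataclass(frozen=True)
class PrecisionRecord:
    """Replicate precision of one sample: CV and corrected CV*."""

    sample_id: str
    n_replicates: int
    mean: float
    sd: float
    cv: float
    cv_star: float


def cv_star(replicate_values, sample_id: str = "") -> PrecisionRecord:
    """Modified coefficient of variation CV* = CV (1 + 1/(4n)).

    CV = sample SD / mean over the n replicate measurements.
    """
    x = np.asarray(replicate_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(x.mean())
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = float(x.std(ddof=1))
    cv = sd / abs(mean)
    n = x.size
    return PrecisionRecord(
        sample_id=sample_id,
        n_replicates=n,
        mean=mean,
        sd=sd,
        cv=cv,
        cv_star=cv * (1.0 + 1.0 / (4.0 * n)),
    )


def rpd_rer(sd_reference: float, range_reference: float, rmsep: float) -> tuple[float, float, str]:
    """Ratio of predictive deviation and range error ratio, with the
    conventional interpretation band.

    RPD = SD/RMSEP, RER = range/RMSEP.  RPD < 2: poor; 2–2.5: screening;
    > 2.5 or RER > 10: quantification; > 3 or RER > 20: accurate
    quantification.
    """
    if sd_reference <= 0 or range_reference <= 0 or rmsep <= 0:
        raise ValueError("SD, range and RMSEP must all be positive")
    rpd = sd_reference / rmsep
    rer = range_reference / rmsep
    if rpd > 3.0 or rer > 20.0:
        label = RPD_ACCURATE
    elif rpd > 2.5 or rer > 10.0:
        label = RPD_QUANTIFICATION
    elif rpd >= 2.0:
        label = RPD_SCREENING
    else:
        label = RPD_POOR
    return float(rpd), float(rer), label


def classify_ftpi(igg: float, cutoff: float = FTPI_CUTOFF) -> bool:
    """FTPI-positive iff IgG is strictly below the cut-off."""
    if igg < 0:
        raise ValueError("IgG concentration cannot be negative")
    return igg < cutoff


@dataclass(frozen=True)
class DiagnosticTable:
    """2x2 diagnostic characteristics of the assay against the reference.

    Undefined rates (zero denominator) are reported as NaN, never as zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float = FTPI_CUTOFF
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    true_prevalence: float = field(init=False)
    apparent_prevalence: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("counts must be non-negative")
        n = self.n
        if n == 0:
            raise ValueError("empty table")

        def ratio(num: int, den: int) -> float:
            return num / den if den > 0 else math.nan

        object.__setattr__(self, "sensitivity", ratio(self.tp, self.tp + self.fn))
        object.__setattr__(self, "specificity", ratio(self.tn, self.tn + self.fp))
        object.__setattr__(self, "accuracy", (self.tp + self.tn) / n)
        object.__setattr__(self, "true_prevalence", (self.tp + self.fn) / n)
        object.__setattr__(self, "apparent_prevalence", (self.tp + self.fp) / n)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int, cutoff: float = FTPI_CUTOFF):
        return cls(tp=tp, fp=fp, tn=tn, fn=fn, cutoff=cutoff)

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["n"] = self.n
        return doc


def diagnostic_table(reference, predicted, cutoff: float = FTPI_CUTOFF) -> DiagnosticTable:
    """Cross-tabulate FTPI status (IgG < cutoff) by reference and assay."""
    r, p = _paired(reference, predicted, min_len=1)
    # predicted concentrations can legitimately come out slightly negative;
    # classification only needs the comparison against the cut-off
    ref_pos = r < cutoff
    test_pos = p < cutoff
    return DiagnosticTable(
        tp=int(np.sum(ref_pos & test_pos)),
        fp=int(np.sum(~ref_pos & test_pos)),
        tn=int(np.sum(~ref_pos & ~test_pos)),
        fn=int(np.sum(ref_pos & ~test_pos)),
        cutoff=cutoff,
    )


@dataclass(frozen=True)
class AgreementReport:
    """All agreement metrics between the reference assay and the calibration.

    RMSEC/calibration metrics describe the refit model on its own training
    data; everything else (RMSEP, CCC, Bland–Altman, RPD/RER) describes the
    held-out prediction set.
    """

    rmsec: float
    rmsep: float
    pearson_r_calibration: float
    pearson_r: float
    ccc_calibration: float
    ccc: float
    bland_altman: tuple[float, float, float]
    rpd: float
    rer: float
    rpd_interpretation: str
    sd_reference: float           # population SD of prediction-set reference
    sd_reference_sample: float    # sample (n-1) SD, reported alongside
    range_reference: float

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["bland_altman"] = {
            "mean_diff": self.bland_altman[0],
            "loa_low": self.bland_altman[1],
            "loa_high": self.bland_altman[2],
        }
        return doc


def evaluate_agreement(
    y_cal, yhat_cal, y_pred, yhat_pred
) -> AgreementReport:
    """Assemble the full agreement report from calibration- and
    prediction-set reference/predicted pairs."""
    y_cal, yhat_cal = _paired(y_cal, yhat_cal, min_len=2)
    y_pred, yhat_pred = _paired(y_pred, yhat_pred, min_len=2)
    rmsep = rmse(y_pred, yhat_pred)
    sd_pop = float(np.std(y_pred))
    sd_sample = float(np.std(y_pred, ddof=1))
    rng_ref = float(np.ptp(y_pred))
    rpd, rer, label = rpd_rer(sd_pop, rng_ref, rmsep)
    return AgreementReport(
        rmsec=rmse(y_cal, yhat_cal),
        rmsep=rmsep,
        pearson_r_calibration=pearson(y_cal, yhat_cal),
        pearson_r=pearson(y_pred, yhat_pred),
        ccc_calibration=concordance_ccc(y_cal, yhat_cal),
        ccc=concordance_ccc(y_pred, yhat_pred),
        bland_altman=bland_altman(y_pred, yhat_pred),
        rpd=rpd,
        rer=rer,
        rpd_interpretation=label,
        sd_reference=sd_pop,
        sd_reference_sample=sd_sample,
        range_reference=rng_ref,
    )


# ---------------------------------------------------------------------------
# Optional plots (scatter, Bland–Altman, CV*); matplotlib imported lazily
# ---------------------------------------------------------------------------

def plot_agreement(y_cal, yhat_cal, y_pred, yhat_pred, destination) -> None:
    """Reference-vs-predicted scatter for calibration and prediction sets."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(y_cal, yhat_cal, marker="s", s=18, label="calibration", alpha=0.7)
    ax.scatter(y_pred, yhat_pred, marker="o", s=18, label="prediction", alpha=0.7)
    lim = [0, max(np.max(y_cal), np.max(y_pred)) * 1.05]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel("reference IgG (mg/dL)")
    ax.set_ylabel("predicted IgG (mg/dL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(destination)
    plt.close(fig)


def plot_bland_altman(reference, test, destination) -> None:
    """Difference-vs-mean plot with the 95% limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = np.asarray(reference, float)
    t = np.asarray(test, float)
    mean_diff, lo, hi = bland_altman(r, t)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((r + t) / 2, t - r, s=18, alpha=0.7)
    ax.axhline(mean_diff, color="k")
    ax.axhline(lo, color="k", ls="--")
    ax.axhline(hi, color="k", ls="--")
    ax.set_xlabel("mean of methods (mg/dL)")
    ax.set_ylabel("test - reference (mg/dL)")
    fig.tight_layout()
    fig.savefig(destination)
    plt.close(fig)


def plot_cv_star(records, destination) -> None:
    """CV* against mean replicate concentration, one point per sample."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = [r.mean for r in records]
    cvs = [r.cv_star for r in records]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, cvs, s=18, alpha=0.7)
    if cvs:
        ax.axhline(float(np.mean(cvs)), color="k", ls="--")
    ax.set_xlabel("mean IgG (mg/dL)")
    ax.set_ylabel("CV*")
    fig.tight_layout()
    fig.savefig(destination)
    plt.close(fig)
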