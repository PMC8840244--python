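"""Evaluation standards for cuffless blood-pressure estimators.

Implements the field's full reporting stack on aligned prediction /
ground-truth vectors (mmHg):

* mean absolute error (MAE), mean error (ME) and its sample SD;
* the British Hypertension Society (BHS) cumulative-error grading —
  percentages of absolute errors <= 5 / 10 / 15 mmHg, grade A requiring
  >= 60 / 85 / 95 %, B >= 50 / 75 / 90 %, C >= 40 / 65 / 85 %, else D,
  with all three thresholds required simultaneously;
* the AAMI compliance rule: |ME| <= 5 mmHg, error SD <= 8 mmHg, and at
  least 85 distinct subjects (all bounds inclusive);
* Bland-Altman agreement: mean difference mu, sample SD sigma, and 95%
  limits of agreement mu +/- 1.96 sigma;
* least-squares linear fit and the sample Pearson correlation.

Sign convention: differences are prediction minus ground truth, and the
sample (n-1) standard deviation is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

BHS_TABLE = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass(frozen=True)
class ErrorVector:
    """Aligned true/predicted mmHg vectors with differences precomputed."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        yt = np.asarray(self.y_true, dtype=np.float64)
        yp = np.asarray(self.y_pred, dtype=np.float64)
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_pred", yp)
        if yt.shape != yp.shape or yt.ndim != 1 or yt.size < 1:
            raise ValueError(f"need aligned 1-D vectors, got {yt.shape} vs {yp.shape}")
        if not (np.all(np.isfinite(yt)) and np.all(np.isfinite(yp))):
            raise ValueError("non-finite values in error vector")

    @property
    def diffs(self) -> np.ndarray:
        return self.y_pred - self.y_true

    @property
    def abs_diffs(self) -> np.ndarray:
        return np.abs(self.diffs)

    def __len__(self) -> int:
        return int(self.y_true.size)


def mae(ev: ErrorVector) -> float:
    """Mean absolute error in mmHg."""
    return float(ev.abs_diffs.mean())


@dataclass(frozen=True)
class BHSReport:
    pct_le_5: float
    pct_le_10: float
    pct_le_15: float
    grade: str

    def __post_init__(self) -> None:
        if not (0 <= self.pct_le_5 <= self.pct_le_10 <= self.pct_le_15 <= 100):
            raise ValueError("cumulative percentages must be nested in [0, 100]")


def bhs_grade(ev: ErrorVector) -> BHSReport:
    """Cumulative absolute-error percentages at 5/10/15 mmHg and the grade."""
    a = ev.abs_diffs
    pcts = tuple(float(100.0 * np.mean(a <= thr)) for thr in (5.0, 10.0, 15.0))
    grade = "D"
    for g in ("A", "B", "C"):
        if all(p >= req for p, req in zip(pcts, BHS_TABLE[g])):
            grade = g
            break
    return BHSReport(*pcts, grade)


@dataclass(frozen=True)
class AAMIReport:
    me: float
    std: float
    n_subjects: int
    passed: bool


def aami_check(ev: ErrorVector, n_subjects: int) -> AAMIReport:
    """Mean error, sample SD, and the compliance verdict."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    me = float(ev.diffs.mean())
    std = float(ev.diffs.std(ddof=1)) if len(ev) > 1 else 0.0
    passed = abs(me) <= 5.0 and std <= 8.0 and n_subjects >= 85
    return AAMIReport(me, std, int(n_subjects), passed)


@dataclass(frozen=True)
class AgreementReport:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float | None = None
    slope: float | None = None
    intercept: float | None = None


def bland_altman(ev: ErrorVector) -> AgreementReport:
    """Mean difference, sample SD and the 95% limits of agreement."""
    if len(ev) < 2:
        raise ValueError("agreement analysis needs at least 2 pairs")
    mu = float(ev.diffs.mean())
    sigma = float(ev.diffs.std(ddof=1))
    return AgreementReport(mu, sigma, mu - 1.96 * sigma, mu + 1.96 * sigma)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Least-squares (intercept, slope) of y on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if x.std() == 0:
        raise ValueError("fit undefined for a constant regressor")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


@dataclass(frozen=True)
class EvalReport:
    """Bundle of every standard metric for one BP target."""

    target: str
    mae: float
    me: float
    std: float
    bhs: BHSReport
    aami: AAMIReport
    agreement: AgreementReport
    n: int
    n_subjects: int

    def to_dict(self, decimals: int = 3) -> dict:
        r = lambda v: round(float(v), decimals)
        return {
            "target": self.target,
            "n": self.n,
            "n_subjects": self.n_subjects,
            "mae": r(self.mae),
            "me": r(self.me),
            "std": r(self.std),
            "bhs": {
                "pct_le_5": r(self.bhs.pct_le_5),
                "pct_le_10": r(self.bhs.pct_le_10),
                "pct_le_15": r(self.bhs.pct_le_15),
                "grade": self.bhs.grade,
            },
            "aami": {
                "me": r(self.aami.me),
                "std": r(self.aami.std),
                "n_subjects": self.aami.n_subjects,
                "passed": self.aami.passed,
            },
            "bland_altman": {
                "mean_diff": r(self.agreement.mean_diff),
                "sd_diff": r(self.agreement.sd_diff),
                "loa_low": r(self.agreement.loa_low),
                "loa_high": r(self.agreement.loa_high),
            },
            "pearson_r": None if self.agreement.pearson_r is None else r(self.agreement.pearson_r),
            "slope": None if self.agreement.slope is None else r(self.agreement.slope),
            "intercept": None if self.agreement.intercept is None else r(self.agreement.intercept),
        }


def evaluate(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    subject_ids: Sequence[str] | None = None,
    target: str = "SBP",
) -> EvalReport:
    """Compute the full report for one target.

    ``subject_ids`` determines the distinct-subject count for the AAMI
    verdict; when omitted every segment counts as its own subject.
    """
    ev = ErrorVector(np.asarray(y_true), np.asarray(y_pred))
    n_subjects = len(set(subject_ids)) if subject_ids is not None else len(ev)
    agreement = bland_altman(ev) if len(ev) >= 2 else AgreementReport(
        float(ev.diffs.mean()), 0.0, float(ev.diffs.mean()), float(ev.diffs.mean())
    )
    try:
        r = pearson_r(ev.y_true, ev.y_pred)
        b0, b1 = linear_fit(ev.y_true, ev.y_pred)
    except ValueError:
        r, b0, b1 = None, None, None
    agreement = AgreementReport(
        agreement.mean_diff, agreement.sd_diff, agreement.loa_low, agreement.loa_high,
        pearson_r=r, slope=b1, intercept=b0,
    )
    aami = aami_check(ev, n_subjects)
    return EvalReport(
        target=target,
        mae=mae(ev),
        me=aami.me,
        std=aami.std,
        bhs=bhs_grade(ev),
        aami=aami,
        agreement=agreement,
        n=len(ev),
        n_subjects=n_subjects,
    )


def plot_agreement(ev: ErrorVector, path: str, target: str = "SBP") -> None:
    """Write regression and Bland-Altman panels to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(ev.y_true, ev.y_pred, s=4, alpha=0.4)
    b0, b1 = linear_fit(ev.y_true, ev.y_pred)
    xs = np.linspace(ev.y_true.min(), ev.y_true.max(), 10)
    ax1.plot(xs, b0 + b1 * xs, "r-", lw=1)
    ax1.set_xlabel(f"true {target} (mmHg)")
    ax1.set_ylabel(f"predicted {target} (mmHg)")
    rep = bland_altman(ev)
    means = (ev.y_true + ev.y_pred) / 2
    ax2.scatter(means, ev.diffs, s=4, alpha=0.4)
    for yv, style in ((rep.mean_diff, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax2.axhline(yv, color="k", ls=style, lw=1)
    ax2.set_xlabel(f"mean {target} (mmHg)")
    ax2.set_ylabel("prediction - truth (mmHg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
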