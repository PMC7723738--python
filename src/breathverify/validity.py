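"""Clustered diagnostic-validity statistics.

A breath-CO monitor is validated against a gold standard (a commercial
CO meter, or urine cotinine) on repeated tests from the same
participants, so every statistic here must respect the clustering:
sensitivity and specificity with cluster-aware confidence intervals
(ratio-estimator Taylor linearization over participant totals, or a
seeded participant-level bootstrap), within-subject repeated-measures
correlation via the ANCOVA formulation, ROC/AUC with a DeLong interval,
and GEE group comparisons with a chosen working correlation.

The modelling surface follows the familiar model/results split:
``DiagnosticValidity(ledger).fit()`` returns a :class:`ValidityResults`
carrying the estimates, their intervals and a ``summary()`` table.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

import statsmodels.api as sm

from . import classify as _classify

__all__ = [
    "DiagnosticValidity",
    "ValidityResults",
    "clustered_sens_spec",
    "rm_correlation",
    "roc_auc",
    "gee_compare",
    "summarize_ledger",
    "LedgerSummary",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


# ---------------------------------------------------------------------------
# sensitivity / specificity with clustered CIs


def _ratio_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """Taylor-linearized CI for the ratio of cluster totals sum(x)/sum(y).

    ``x``/``y`` are per-cluster numerators and denominators.  Returns
    (point, lo, hi, degenerate) with bounds clipped to [0, 1].
    """
    X, Y = x.sum(), y.sum()
    if Y == 0:
        raise ValueError("ratio undefined: no denominator events")
    r = X / Y
    m = len(x)
    if m < 2:
        return r, r, r, True
    resid = x - r * y
    var = m / (m - 1) * np.sum(resid**2) / Y**2
    half = sps.norm.ppf(1 - alpha / 2) * np.sqrt(var)
    return r, float(np.clip(r - half, 0, 1)), float(np.clip(r + half, 0, 1)), False


def _bootstrap_ratio_ci(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_boot: int = 2000,
    alpha: float = 0.05,
):
    """Percentile CI from resampling clusters (their totals) with replacement."""
    m = len(x)
    r = x.sum() / y.sum()
    if m < 2:
        return r, r, r, True
    idx = rng.integers(0, m, size=(n_boot, m))
    num = x[idx].sum(axis=1)
    den = y[idx].sum(axis=1)
    ok = den > 0
    ratios = num[ok] / den[ok]
    lo, hi = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    return r, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)), False


def clustered_sens_spec(
    ledger: pd.DataFrame,
    method: str = "ratio_estimator",
    index_col: str = "index_status",
    reference_col: str = "reference_status",
    cluster_col: str = "participant_id",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> dict:
    """Sensitivity and specificity of an index test with cluster-aware CIs.

    Statuses are binary with 1 (or "smoking") = positive.  ``method`` is
    ``ratio_estimator`` (Taylor linearization over participant totals)
    or ``cluster_bootstrap`` (participant-level percentile bootstrap,
    seeded).  Raises when the reference has no positives (sensitivity
    undefined) or no negatives (specificity undefined).
    """
    df = ledger[[cluster_col, index_col, reference_col]].dropna().copy()
    idx = _as_binary(df[index_col])
    ref = _as_binary(df[reference_col])
    df = pd.DataFrame({"cluster": df[cluster_col], "idx": idx, "ref": ref})
    if df["ref"].sum() == 0:
        raise ValueError("sensitivity undefined: reference has no positives")
    if (1 - df["ref"]).sum() == 0:
        raise ValueError("specificity undefined: reference has no negatives")

    per = df.groupby("cluster").apply(
        lambda g: pd.Series(
            {
                "tp": ((g.idx == 1) & (g.ref == 1)).sum(),
                "pos": (g.ref == 1).sum(),
                "tn": ((g.idx == 0) & (g.ref == 0)).sum(),
                "neg": (g.ref == 0).sum(),
            }
        ),
        include_groups=False,
    )
    degenerate = False
    if method == "ratio_estimator":
        sens, s_lo, s_hi, d1 = _ratio_ci(
            per["tp"].to_numpy(float), per["pos"].to_numpy(float), alpha
        )
        spec, p_lo, p_hi, d2 = _ratio_ci(
            per["tn"].to_numpy(float), per["neg"].to_numpy(float), alpha
        )
        degenerate = d1 or d2
    elif method == "cluster_bootstrap":
        rng = np.random.default_rng(seed)
        sens, s_lo, s_hi, d1 = _bootstrap_ratio_ci(
            per["tp"].to_numpy(float), per["pos"].to_numpy(float), rng, n_boot, alpha
        )
        spec, p_lo, p_hi, d2 = _bootstrap_ratio_ci(
            per["tn"].to_numpy(float), per["neg"].to_numpy(float), rng, n_boot, alpha
        )
        degenerate = d1 or d2
    else:
        raise ValueError(f"unknown method {method!r}")
    if degenerate:
        _warnings.warn(
            "single cluster: interval degenerates to the point estimate",
            stacklevel=2,
        )
    return {
        "sensitivity": float(sens),
        "sensitivity_ci": (s_lo, s_hi),
        "specificity": float(spec),
        "specificity_ci": (p_lo, p_hi),
        "n_clusters": int(per.shape[0]),
        "n_pairs": int(df.shape[0]),
    }


def _as_binary(s: pd.Series) -> pd.Series:
    if s.dtype == object or isinstance(s.dtype, pd.StringDtype):
        return (s.astype(str) == _classify.SMOKING).astype(int)
    return s.astype(int)


# ---------------------------------------------------------------------------
# repeated-measures (within-subject) correlation


def rm_correlation(
    ledger: pd.DataFrame,
    x: str,
    y: str,
    cluster_col: str = "participant_id",
) -> tuple[float, float]:
    """Within-participant correlation of two repeated measures.

    ANCOVA formulation: regress ``y`` on ``x`` with participant-specific
    intercepts and a common slope; ``r`` is the signed square root of
    the share of within-participant variance explained by ``x`` and the
    p-value comes from the corresponding F(1, N - k - 1) statistic.
    Computed from within-centered sums of squares.
    """
    df = ledger[[cluster_col, x, y]].dropna()
    if df.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    g = df.groupby(cluster_col)
    xc = (df[x] - g[x].transform("mean")).to_numpy(float)
    yc = (df[y] - g[y].transform("mean")).to_numpy(float)
    sxx = float(np.sum(xc**2))
    if sxx == 0:
        raise ValueError("x is constant within every participant")
    sxy = float(np.sum(xc * yc))
    syy = float(np.sum(yc**2))
    ss_reg = sxy**2 / sxx
    ss_err = syy - ss_reg
    k = df[cluster_col].nunique()
    dof = df.shape[0] - k - 1
    if dof <= 0:
        raise ValueError("not enough observations for the within-subject fit")
    r = float(np.sign(sxy) * np.sqrt(ss_reg / syy)) if syy > 0 else 0.0
    if ss_err <= 0:  # perfect within-subject linearity
        return r, 0.0
    f_stat = ss_reg / (ss_err / dof)
    p = float(sps.f.sf(f_stat, 1, dof))
    return r, p


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong interval


def _midrank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong's AUC point estimate and variance via midranks."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(all_scores)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_auc(
    ledger: pd.DataFrame,
    score_col: str = "index_value",
    reference_col: str = "reference_status",
    alpha: float = 0.05,
) -> dict:
    """ROC curve and AUC of a continuous score against a binary reference.

    AUC is the Mann-Whitney pair-counting probability (ties count 1/2);
    the confidence interval is DeLong's, clipped to [0, 1]; curve
    points are given at every distinct threshold.
    """
    df = ledger[[score_col, reference_col]].dropna()
    ref = _as_binary(df[reference_col]).to_numpy()
    score = df[score_col].to_numpy(float)
    if ref.sum() == 0 or ref.sum() == len(ref):
        raise ValueError("AUC undefined: reference contains a single class")
    auc, var = _delong_variance(score[ref == 1], score[ref == 0])
    half = sps.norm.ppf(1 - alpha / 2) * np.sqrt(var)
    fpr, tpr, thresholds = roc_curve(ref, score)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return {
        "auc": auc,
        "auc_ci": (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))),
        "curve": curve,
    }


# ---------------------------------------------------------------------------
# GEE group comparison


_COV_STRUCTS = {
    "ar1": lambda: sm.cov_struct.Autoregressive(grid=True),
    "independence": sm.cov_struct.Independence,
    "exchangeable": sm.cov_struct.Exchangeable,
}


def gee_compare(
    ledger: pd.DataFrame,
    outcome: str,
    group: str,
    covariates: list[str] | None = None,
    correlation: str = "ar1",
    cluster_col: str = "participant_id",
    time_col: str | None = None,
    cov_type: str = "bias_reduced",
) -> dict:
    """Marginal group comparison of a continuous outcome under clustering.

    Generalized estimating equations with identity link (Gaussian
    family), a cluster-robust sandwich covariance and the requested
    working correlation.  ``ar1`` treats within-participant rows as an
    evenly spaced series, so they must be time-ordered; pass
    ``time_col`` to sort them first.

    With the handful of clusters typical of pilot studies the plain
    sandwich is anticonservative, so the default covariance is the
    bias-reduced (Mancl-DeRouen) estimator and p-values use a t
    reference with (clusters - parameters) degrees of freedom; set
    ``cov_type='robust'`` for the asymptotic sandwich.  Returns the
    group coefficient, its robust SE and the two-sided p.
    """
    if correlation not in _COV_STRUCTS:
        raise ValueError(f"unknown working correlation {correlation!r}")
    covariates = covariates or []
    cols = [cluster_col, outcome, group] + covariates
    if time_col:
        cols.append(time_col)
    df = ledger[cols].dropna().copy()
    if time_col:
        df = df.sort_values([cluster_col, time_col], kind="stable")
    gvals = df[group]
    if gvals.nunique() < 2:
        raise ValueError("group variable is constant")
    if not np.issubdtype(np.asarray(gvals).dtype, np.number):
        df[group] = (gvals == gvals.unique()[1]).astype(int)

    exog = sm.add_constant(df[[group] + covariates].astype(float))
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("singular design matrix")
    model = sm.GEE(
        df[outcome].astype(float),
        exog,
        groups=df[cluster_col],
        family=sm.families.Gaussian(),
        cov_struct=_COV_STRUCTS[correlation](),
    )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(cov_type=cov_type)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"GEE did not converge: params={res.params.to_dict()}")
    m = int(df[cluster_col].nunique())
    dof = m - exog.shape[1]
    coef = float(res.params[group])
    se = float(res.bse[group])
    if dof > 0:
        p = float(2.0 * sps.t.sf(abs(coef / se), dof))
    else:
        p = float(res.pvalues[group])
    return {
        "coefficient": coef,
        "robust_se": se,
        "p_value": p,
        "n_clusters": m,
        "df": dof,
        "results": res,
    }


# ---------------------------------------------------------------------------
# ledger summary (counts and printed-precision proportions)


@dataclass
class LedgerSummary:
    """Counts and proportions describing one study ledger.

    Percentages are rounded half away from zero at the precision a
    clinical report prints them: one decimal for the in-office recency
    split and remote completion, integers for the remote-outcome
    breakdowns.
    """

    n_participants: int = 0
    n_in_office: int = 0
    recency_within: int = 0
    recency_beyond: int = 0
    recency_missing: int = 0
    recency_within_pct: float = float("nan")
    recency_beyond_pct: float = float("nan")
    recency_missing_pct: float = float("nan")
    n_remote_sent: int = 0
    n_remote_completed: int = 0
    remote_completed_pct: float = float("nan")
    remote_completed_smoking: int = 0
    remote_completed_smoking_pct: float = float("nan")
    n_remote_missed: int = 0
    missed_preceded_by_positive: int = 0
    missed_preceded_by_positive_pct: float = float("nan")
    n_delivery_failed: int = 0
    delivery_failed_pct: float = float("nan")
    n_challenged: int = 0
    challenged_pct: float = float("nan")
    mean_tests_per_participant: float = float("nan")
    per_participant_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("per_participant_counts")
        return d


def summarize_ledger(
    ledger: pd.DataFrame,
    co_cutoff: float = _classify.CO_CUTOFF_PPM,
    decimals: int = 1,
) -> LedgerSummary:
    """Counts and printed-precision proportions for a classified ledger.

    Needs ``recency`` and ``status_momba`` columns (see
    :func:`breathverify.classify.classify_ledger`); computes them from
    the raw columns when absent.  An empty ledger yields an empty
    summary rather than an error.
    """
    s = LedgerSummary()
    if ledger.empty:
        return s
    df = ledger
    if "recency" not in df.columns or "status_momba" not in df.columns:
        df = _classify.classify_ledger(df, co_cutoff=co_cutoff)

    s.n_participants = int(df["participant_id"].nunique())
    office = df[df["setting"] == "in_office"]
    s.n_in_office = int(office.shape[0])
    if s.n_in_office:
        s.recency_within = int((office["recency"] == _classify.WITHIN).sum())
        s.recency_beyond = int((office["recency"] == _classify.BEYOND).sum())
        s.recency_missing = int((office["recency"] == _classify.MISSING).sum())
        s.recency_within_pct = round_half_up(
            100.0 * s.recency_within / s.n_in_office, decimals
        )
        s.recency_beyond_pct = round_half_up(
            100.0 * s.recency_beyond / s.n_in_office, decimals
        )
        s.recency_missing_pct = round_half_up(
            100.0 * s.recency_missing / s.n_in_office, decimals
        )
        counts = office.groupby("participant_id").size()
        s.per_participant_counts = counts.to_dict()
        s.mean_tests_per_participant = round_half_up(
            float(counts.sum()) / s.n_participants, decimals
        )

    remote = df[df["setting"] == "remote"]
    s.n_remote_sent = int(remote.shape[0])
    if s.n_remote_sent:
        completed = remote[remote["notification_status"] == "completed"]
        missed = remote[remote["notification_status"] != "completed"]
        s.n_remote_completed = int(completed.shape[0])
        s.remote_completed_pct = round_half_up(
            100.0 * s.n_remote_completed / s.n_remote_sent, decimals
        )
        if s.n_remote_completed:
            s.remote_completed_smoking = int(
                (completed["status_momba"] == _classify.SMOKING).sum()
            )
            s.remote_completed_smoking_pct = round_half_up(
                100.0 * s.remote_completed_smoking / s.n_remote_completed
            )
            s.n_challenged = int((completed["challenged"] == True).sum())  # noqa: E712
            s.challenged_pct = round_half_up(
                100.0 * s.n_challenged / s.n_remote_completed
            )
        s.n_remote_missed = int(missed.shape[0])
        if s.n_remote_missed:
            s.missed_preceded_by_positive = _count_preceded_by_positive(df, missed)
            s.missed_preceded_by_positive_pct = round_half_up(
                100.0 * s.missed_preceded_by_positive / s.n_remote_missed
            )
            s.n_delivery_failed = int(
                (missed["notification_status"] == "delivery_failed").sum()
            )
            s.delivery_failed_pct = round_half_up(
                100.0 * s.n_delivery_failed / s.n_remote_missed
            )
    return s


def _count_preceded_by_positive(df: pd.DataFrame, missed: pd.DataFrame) -> int:
    """How many missed remote tests follow a smoking-positive completed test."""
    count = 0
    completed = df[df["status_momba"].notna()]
    for _, row in missed.iterrows():
        prior = completed[
            (completed["participant_id"] == row["participant_id"])
            & (completed["timestamp"] < row["timestamp"])
        ].sort_values("timestamp", kind="stable")
        if not prior.empty and prior.iloc[-1]["status_momba"] == _classify.SMOKING:
            count += 1
    return count


# ---------------------------------------------------------------------------
# model / results surface


class DiagnosticValidity:
    """Validity of an index smoking test against a gold standard.

    Built from a classified study ledger; ``fit()`` computes clustered
    sensitivity/specificity, the repeated-measures correlation of the
    underlying values, and ROC/AUC, and returns a
    :class:`ValidityResults`.

    Parameters
    ----------
    ledger : classified ledger (see :func:`breathverify.classify.classify_ledger`)
    index : "momba" or "pico" — the device under evaluation
    reference : "pico" or "cotinine" — the gold standard
    """

    _VALUE_COLS = {"momba": "momba_ppm", "pico": "pico_ppm", "cotinine": "cotinine_ng_ml"}

    def __init__(self, ledger: pd.DataFrame, index: str = "momba", reference: str = "pico"):
        if index == reference:
            raise ValueError("index and reference must differ")
        for name in (index, reference):
            if name not in self._VALUE_COLS:
                raise ValueError(f"unknown measure {name!r}")
        self.index = index
        self.reference = reference
        needed = {
            self._VALUE_COLS[index],
            self._VALUE_COLS[reference],
            f"status_{index}",
            f"status_{reference}",
            "participant_id",
        }
        missing = needed - set(ledger.columns)
        if missing:
            raise ValueError(f"ledger missing columns: {sorted(missing)}")
        df = ledger.dropna(
            subset=[self._VALUE_COLS[index], self._VALUE_COLS[reference]]
        ).copy()
        self.data = pd.DataFrame(
            {
                "participant_id": df["participant_id"],
                "index_value": df[self._VALUE_COLS[index]].astype(float),
                "reference_value": df[self._VALUE_COLS[reference]].astype(float),
                "index_status": _as_binary(df[f"status_{index}"]),
                "reference_status": _as_binary(df[f"status_{reference}"]),
            }
        )

    @classmethod
    def from_dataframe(cls, ledger: pd.DataFrame, index: str = "momba",
                       reference: str = "pico") -> "DiagnosticValidity":
        return cls(ledger, index=index, reference=reference)

    def fit(
        self,
        ci_method: str = "ratio_estimator",
        n_boot: int = 2000,
        seed: int | None = 0,
        alpha: float = 0.05,
    ) -> "ValidityResults":
        ss = clustered_sens_spec(
            self.data, method=ci_method, alpha=alpha, n_boot=n_boot, seed=seed
        )
        r, p = rm_correlation(self.data, "index_value", "reference_value")
        roc = roc_auc(self.data, "index_value", "reference_status", alpha=alpha)
        return ValidityResults(
            index=self.index,
            reference=self.reference,
            sensitivity=ss["sensitivity"],
            sensitivity_ci=ss["sensitivity_ci"],
            specificity=ss["specificity"],
            specificity_ci=ss["specificity_ci"],
            r=r,
            r_pvalue=p,
            auc=roc["auc"],
            auc_ci=roc["auc_ci"],
            curve=roc["curve"],
            n_pairs=ss["n_pairs"],
            n_clusters=ss["n_clusters"],
            ci_method=ci_method,
        )


@dataclass
class ValidityResults:
    """Fitted diagnostic-validity estimates for one device comparison."""

    index: str
    reference: str
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    r: float
    r_pvalue: float
    auc: float
    auc_ci: tuple[float, float]
    curve: pd.DataFrame
    n_pairs: int
    n_clusters: int
    ci_method: str

    def summary(self) -> str:
        """Validity table in the layout of a clinical report."""
        ci = lambda c: f"({c[0]:.2f}-{c[1]:.2f})"
        lines = [
            f"Diagnostic validity: {self.index} vs {self.reference} (gold standard)",
            f"  n = {self.n_pairs} paired tests from {self.n_clusters} participants",
            f"  CI method: {self.ci_method} (cluster-aware, 95%)",
            f"  Sensitivity  {self.sensitivity:.2f} {ci(self.sensitivity_ci)}",
            f"  Specificity  {self.specificity:.2f} {ci(self.specificity_ci)}",
            f"  r (within-subject)  {self.r:.2f}  P = {self.r_pvalue:.3g}",
            f"  AUC  {self.auc:.2f} {ci(self.auc_ci)}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "reference": self.reference,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "r": self.r,
            "r_pvalue": self.r_pvalue,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "n_pairs": self.n_pairs,
            "n_clusters": self.n_clusters,
            "ci_method": self.ci_method,
        }

    def plot_roc(self, ax=None):
        """ROC curve (true-positive vs false-positive fraction)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.curve["fpr"], self.curve["tpr"], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("False-positive fraction")
        ax.set_ylabel("True-positive fraction")
        ax.set_title(f"{self.index} vs {self.reference}: AUC {self.auc:.2f}")
        return ax
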