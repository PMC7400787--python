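"""Cohort stratification: UVMSE threshold, TMB categories, outcome tests.

Patients carrying a per-sample UVMSE score are dichotomized at a threshold
(score >= threshold = "UV high"); tumor mutational burden (TMB,
mutations/Mb) is binned low (1-5), intermediate (6-19) or high (>= 20).
Best RECIST response is collapsed to responder (CR/PR) vs non-responder
(SD/PD).  The univariate statistics reported are the Fisher exact odds
ratio for response, and Kaplan-Meier medians with a Mantel-Cox log-rank
test for progression-free and overall survival.  The stratified report
contrasts UV-high vs UV-low separately within the pooled low/intermediate
TMB stratum and the high TMB stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

RESPONDER_CLASSES = frozenset({"CR", "PR"})
NONRESPONDER_CLASSES = frozenset({"SD", "PD"})

#: Published reference cutoffs: 0.7917 separates UV-high/-low on
#: gene-panel-restricted scores of an immunotherapy cohort; 1.642 is the
#: analogous whole-exome acral-vs-cutaneous melanoma cutoff.  Shipped as
#: documented defaults only; both depend on the underlying cohorts and are
#: not reproducible from synthetic data.
DEFAULT_UVMSE_THRESHOLD = 0.7917
WHOLE_EXOME_UVMSE_THRESHOLD = 1.642


def tmb_category(tmb: float) -> str:
    """TMB bin: low (1-5 mut/Mb, values < 1 folded in), intermediate
    (6-19), high (>= 20)."""
    if tmb < 0:
        raise ValueError("TMB must be >= 0")
    if tmb < 6:
        return "low"
    if tmb < 20:
        return "intermediate"
    return "high"


def roc_threshold(scores, binary_outcome) -> float:
    """Score cutoff maximizing Youden's J (sensitivity + specificity - 1)
    for predicting the positive outcome with score >= threshold.

    Candidate cutoffs are midpoints between adjacent distinct scores, so a
    perfectly separated sample returns the midpoint of the gap.  Ties in J
    resolve to the lowest qualifying cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_outcome, dtype=int)
    if s.size != y.size or s.size == 0:
        raise ValueError("scores and outcomes must be equal-length and non-empty")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(s)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0]], candidates))  # threshold at/below min = all high
    best_t, best_j = None, -np.inf
    n_pos, n_neg = y.sum(), (1 - y).sum()
    for t in candidates:
        pred = s >= t
        j = (pred & (y == 1)).sum() / n_pos - (pred & (y == 0)).sum() / n_neg
        if j > best_j + 1e-12:
            best_t, best_j = float(t), float(j)
    return best_t


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Response-by-group counts: a,b = responders/non-responders in group 1;
    c,d = responders/non-responders in group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class FisherResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool = False


def fisher_odds_ratio(t: ContingencyTable2x2, alpha: float = 0.05) -> FisherResult:
    """Cross-product odds ratio (a*d)/(b*c) with Fisher exact two-sided p
    and a log-OR normal-approximation CI.

    A zero cell triggers the Haldane-Anscombe +0.5 correction for the OR
    and CI (flagged in the result); the exact p-value is unaffected.
    """
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    corrected = 0 in (t.a, t.b, t.c, t.d)
    if corrected:
        table = table + 0.5
    a, b, c, d = table.ravel()
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return FisherResult(
        odds_ratio=float(orr),
        ci_low=float(np.exp(np.log(orr) - z * se)),
        ci_high=float(np.exp(np.log(orr) + z * se)),
        p_value=float(p),
        continuity_corrected=corrected,
    )


@dataclass
class KMResult:
    medians: dict[str, float]  # group -> median survival (NaN = not reached)
    p_value: float
    n_per_group: dict[str, int]


def km_logrank(times, event_flags, groups) -> KMResult:
    """Kaplan-Meier median survival per group plus the Mantel-Cox log-rank
    two-sided p-value.  An undefined (never-crossed) median is returned as
    NaN, conventionally reported 'not reached'."""
    df = pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(event_flags, int), "group": list(groups)}
    )
    if (df["time"] < 0).any():
        raise ValueError("times must be >= 0")
    if df["event"].sum() == 0:
        raise ValueError("need at least one event")
    labels = df["group"].unique()
    if len(labels) < 2 or (df.groupby("group").size() == 0).any():
        raise ValueError("need at least two non-empty groups")
    medians, n_per = {}, {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter().fit(sub["time"], sub["event"])
        med = kmf.median_survival_time_
        medians[g] = float("nan") if np.isinf(med) else float(med)
        n_per[g] = int(len(sub))
    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return KMResult(medians=medians, p_value=float(lr.p_value), n_per_group=n_per)


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV with columns
    ``id uvmse tmb response pfs_months pfs_event os_months os_event [...]``."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "uvmse", "tmb", "response", "pfs_months", "pfs_event", "os_months", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    bad = set(df["response"]) - (RESPONDER_CLASSES | NONRESPONDER_CLASSES)
    if bad:
        raise ValueError(f"unknown response classes {sorted(bad)}")
    return df


def stratified_report(
    cohort: pd.DataFrame,
    threshold: float = DEFAULT_UVMSE_THRESHOLD,
) -> dict[str, dict]:
    """UV-high vs UV-low response OR and PFS/OS log-rank, within the
    low/intermediate and high TMB strata.

    Returns one block per stratum; strata with fewer than two patients in
    either UV group are skipped with a note.
    """
    df = cohort.copy()
    df["uv_high"] = df["uvmse"] >= threshold
    df["responder"] = df["response"].isin(RESPONDER_CLASSES)
    df["tmb_cat"] = df["tmb"].map(tmb_category)
    df["stratum"] = np.where(df["tmb_cat"] == "high", "high", "low/intermediate")
    report: dict[str, dict] = {}
    for stratum, sub in df.groupby("stratum"):
        block: dict = {"n": int(len(sub))}
        n_high, n_low = int(sub["uv_high"].sum()), int((~sub["uv_high"]).sum())
        if min(n_high, n_low) < 2:
            block["note"] = "skipped: fewer than 2 patients in a UV group"
            report[stratum] = block
            continue
        hi, lo = sub[sub["uv_high"]], sub[~sub["uv_high"]]
        table = ContingencyTable2x2(
            a=int(hi["responder"].sum()),
            b=int((~hi["responder"]).sum()),
            c=int(lo["responder"].sum()),
            d=int((~lo["responder"]).sum()),
        )
        block["response_table"] = table
        block["response"] = fisher_odds_ratio(table)
        groups = np.where(sub["uv_high"], "UV high", "UV low")
        for endpoint in ("pfs", "os"):
            try:
                block[endpoint] = km_logrank(
                    sub[f"{endpoint}_months"], sub[f"{endpoint}_event"], groups
                )
            except ValueError as exc:
                block[endpoint] = f"not computed: {exc}"
        report[stratum] = block
    return report
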