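"""Two-round statistical catalogue of TF state selectivity.

Round 1: universal TFs (top-decile mean activity with low variation across
state means) are set aside; every remaining TF is tested per state with an
unpaired t-test on log activity scores (target state vs all other samples;
pooled variance by default, Welch optional), passing at P < 0.05 and log2
fold change > 0.5. TFs passing in
exactly one state are single-state, in two or more multi-state, in none
unclassified. Round 2 refines a focal pair of transcriptionally similar
states (e.g. terminally exhausted vs tissue-resident memory) with the same
test restricted to the two states' samples, splitting the pair's candidates
into each state's single-taskers and shared multi-taskers.

The t-tests act on log scores, justified by the empirical log-normality of
activity scores (checked by :func:`lognormality_fraction`); log2FC is the
difference of mean log2 scores, i.e. the log-ratio of geometric means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pagerank import PageRankMatrix

__all__ = [
    "StateDesign",
    "Thresholds",
    "TFCatalog",
    "find_universal",
    "lognormality_fraction",
    "state_specific_test",
    "classify_tfs",
    "refine_state_pair",
]


@dataclass
class StateDesign:
    """Sample -> state map with a stable state order."""

    design: pd.Series

    def __post_init__(self):
        states = []
        for s in self.design:
            if s not in states:
                states.append(s)
        self.states = states
        if len(states) < 2:
            raise ValueError("need at least 2 states")
        counts = self.design.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"each state needs >= 2 samples; too few in "
                             f"{list(small.index)}")

    def samples_of(self, state: str) -> list[str]:
        return list(self.design.index[self.design == state])


@dataclass
class Thresholds:
    top_frac: float = 0.10
    cv_max: float = 0.5
    p_max: float = 0.05
    lfc_min: float = 0.5
    bh_adjust: bool = False  # off by default: raw-P cutoffs
    welch: bool = False      # pooled-variance unpaired t by default


@dataclass
class TFCatalog:
    """Per-TF class with the statistics behind the calls."""

    classes: pd.Series                 # tf -> universal/single_state/multi_state/unclassified
    state_sets: dict[str, tuple]       # tf -> tuple of passing states
    stats: pd.DataFrame                # rows (tf, state): p_value, log2fc, mean_score, passed
    cv: pd.Series                      # tf -> CV of state means
    universal: set = field(default_factory=set)
    round2: pd.DataFrame | None = None  # tf, p_value, log2fc, verdict

    def members(self, cls: str) -> list[str]:
        return list(self.classes.index[self.classes == cls])

    def single_state_map(self) -> dict[str, str]:
        return {tf: self.state_sets[tf][0] for tf in self.members("single_state")}

    def summary(self) -> dict[str, int]:
        return self.classes.value_counts().to_dict()


def _state_means(pr: PageRankMatrix, design: StateDesign) -> pd.DataFrame:
    cols = {st: pr.scores[design.samples_of(st)].mean(axis=1)
            for st in design.states}
    return pd.DataFrame(cols)


def find_universal(pr: PageRankMatrix, design: StateDesign,
                   top_frac: float = 0.10, cv_max: float = 0.5) -> set:
    """TFs with grand mean activity in the top ``top_frac`` fraction and
    coefficient of variation of state means below ``cv_max``.

    The grand mean averages the per-state means (not raw samples), so
    unbalanced designs do not weight over-sampled states; CV uses the
    sample sd (ddof=1) across state means.
    """
    sm = _state_means(pr, design)
    grand = sm.mean(axis=1)
    zero = grand.index[grand <= 0]
    if len(zero):
        warnings.warn(f"TF(s) with nonpositive grand mean excluded from "
                      f"universal test (CV undefined): {list(zero[:5])}")
    cv = sm.std(axis=1, ddof=1) / grand
    n_top = int(np.ceil(top_frac * len(grand)))
    top = set(grand.drop(zero).nlargest(n_top).index)
    return {tf for tf in top if cv[tf] < cv_max}


def lognormality_fraction(pr: PageRankMatrix, alpha: float = 0.05,
                          ) -> tuple[float, pd.Series]:
    """Fraction of TFs whose log scores pass a Shapiro-Wilk normality test.

    Returns (fraction, per-TF p-values). Constant rows are degenerate and
    counted as failing with p-value NaN.
    """
    if pr.scores.shape[1] < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 samples")
    bad = pr.scores.index[(pr.scores <= 0).any(axis=1)]
    if len(bad):
        raise ValueError(f"nonpositive scores (log undefined) for TF(s): "
                         f"{list(bad[:5])}")
    pvals = {}
    for tf, row in pr.scores.iterrows():
        x = np.log(row.to_numpy(dtype=float))
        if np.ptp(x) == 0:
            pvals[tf] = np.nan
            continue
        pvals[tf] = stats.shapiro(x).pvalue
    pser = pd.Series(pvals, name="shapiro_p")
    frac = float((pser > alpha).mean())
    return frac, pser


def state_specific_test(pr: PageRankMatrix, design: StateDesign, tf: str,
                        state: str, p_max: float = 0.05,
                        lfc_min: float = 0.5, welch: bool = False,
                        ) -> tuple[float, float, bool]:
    """Unpaired t-test of log scores, target state vs all other samples.

    Pooled-variance by default (``welch=True`` switches to the
    unequal-variance form). Returns (p_value, log2FC, pass). log2FC is
    log2 of the ratio of geometric means (target / background); a TF
    passes only in the direction of higher activity in the target state.
    """
    target_samples = design.samples_of(state)
    bg_samples = [s for s in design.design.index if s not in target_samples]
    if len(target_samples) < 2 or len(bg_samples) < 2:
        raise ValueError("both groups need >= 2 samples")
    t = np.log2(pr.scores.loc[tf, target_samples].to_numpy(dtype=float))
    b = np.log2(pr.scores.loc[tf, bg_samples].to_numpy(dtype=float))
    lfc = float(t.mean() - b.mean())
    if np.ptp(t) == 0 and np.ptp(b) == 0:
        p = 1.0 if t.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(t, b, equal_var=not welch).pvalue)
    return p, lfc, bool(p < p_max and lfc > lfc_min)


def classify_tfs(pr: PageRankMatrix, design: StateDesign,
                 thresholds: Thresholds | None = None) -> TFCatalog:
    """Round-1 catalogue: universal first, then per-state specificity tests."""
    th = thresholds or Thresholds()
    universal = find_universal(pr, design, th.top_frac, th.cv_max)
    sm = _state_means(pr, design)
    grand = sm.mean(axis=1)
    cv = sm.std(axis=1, ddof=1) / grand.where(grand > 0)

    rows = []
    for tf in pr.scores.index:
        if tf in universal:
            continue
        for st in design.states:
            p, lfc, ok = state_specific_test(pr, design, tf, st,
                                             th.p_max, th.lfc_min, th.welch)
            rows.append((tf, st, p, lfc, sm.loc[tf, st], ok))
    stats_df = pd.DataFrame(rows, columns=["tf", "state", "p_value",
                                           "log2fc", "mean_score", "passed"])
    if th.bh_adjust and len(stats_df):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(stats_df["p_value"], method="fdr_bh")[1]
        stats_df["p_adj"] = adj
        stats_df["passed"] = (adj < th.p_max) & (stats_df["log2fc"] > th.lfc_min)

    classes = {}
    state_sets: dict[str, tuple] = {}
    for tf in pr.scores.index:
        if tf in universal:
            classes[tf] = "universal"
            state_sets[tf] = ()
            continue
        passed = tuple(stats_df.loc[(stats_df["tf"] == tf)
                                    & stats_df["passed"], "state"])
        state_sets[tf] = passed
        if len(passed) == 0:
            classes[tf] = "unclassified"
        elif len(passed) == 1:
            classes[tf] = "single_state"
        else:
            classes[tf] = "multi_state"
    return TFCatalog(classes=pd.Series(classes, name="class"),
                     state_sets=state_sets, stats=stats_df, cv=cv,
                     universal=universal)


def refine_state_pair(pr: PageRankMatrix, design: StateDesign,
                      catalog: TFCatalog, state_a: str, state_b: str,
                      thresholds: Thresholds | None = None) -> TFCatalog:
    """Round 2: re-test the pair's candidates using only the two states.

    A candidate (a TF classified to state_a, state_b, or both in round 1)
    becomes a single-tasker of whichever state wins the pairwise t-test
    at the same cutoffs; otherwise it is a shared multi-tasker.
    """
    th = thresholds or Thresholds()
    a_samples = design.samples_of(state_a)
    b_samples = design.samples_of(state_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(f"states {state_a!r}/{state_b!r} need >= 2 samples")
    candidates = [tf for tf, ss in catalog.state_sets.items()
                  if state_a in ss or state_b in ss]
    rows = []
    for tf in candidates:
        xa = np.log2(pr.scores.loc[tf, a_samples].to_numpy(dtype=float))
        xb = np.log2(pr.scores.loc[tf, b_samples].to_numpy(dtype=float))
        lfc = float(xa.mean() - xb.mean())
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            p = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=not th.welch).pvalue)
        if p < th.p_max and lfc > th.lfc_min:
            verdict = "first_state"
        elif p < th.p_max and lfc < -th.lfc_min:
            verdict = "second_state"
        else:
            verdict = "shared"
        rows.append((tf, p, lfc, verdict))
    catalog.round2 = pd.DataFrame(rows, columns=["tf", "p_value", "log2fc",
                                                 "verdict"])
    return catalog
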