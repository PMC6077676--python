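"""Challenge scoring, feature ranking, and evaluation protocols.

The scoring function follows the PhysioNet/CinC 2016 convention: each
record carries a reference diagnosis (normal/abnormal) and signal quality
(clean/noisy), the classifier outputs normal (-1), uncertain (0) or
abnormal (+1), and the twelve resulting counts are combined into a
weighted, modified sensitivity/specificity pair.  An "uncertain" decision
counts as correct for noisy records but as an error for clean ones, so the
score rewards classifiers that flag only genuinely unreadable signals.

With per-quality weights

    wa1 = clean abnormal / total abnormal    wa2 = noisy abnormal / total abnormal
    wn1 = clean normal  / total normal       wn2 = noisy normal  / total normal

the scores are

    Se = wa1 * Aa1/(Aa1+Aq1+An1) + wa2 * (Aa2+Aq2)/(Aa2+Aq2+An2)
    Sp = wn1 * Nn1/(Na1+Nq1+Nn1) + wn2 * (Nn2+Nq2)/(Na2+Nq2+Nn2)
    Overall = (Se + Sp) / 2.

This module also implements Pearson-correlation feature ranking and the
repeated stratified-split and per-domain cross-validation experiment
drivers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_prep import FeatureTable
from .model import Decision, PcgSvm, SvmConfig, classify_records

__all__ = [
    "ConfusionCounts",
    "Weights",
    "ScoreReport",
    "RankingReport",
    "tally",
    "compute_weights",
    "score",
    "rank_features",
    "run_split_experiment",
    "run_domain_experiment",
    "derive_seed",
]

logger = logging.getLogger(__name__)

_CELLS = ("Nn1", "Nq1", "Na1", "Nn2", "Nq2", "Na2", "An1", "Aq1", "Aa1", "An2", "Aq2", "Aa2")


def derive_seed(master: int, index: int) -> int:
    """Deterministic sub-seed below 2**31 (splitmix-style ladder)."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


@dataclass
class ConfusionCounts:
    """The 12 cells of the reference-by-decision table.

    First letter: reference diagnosis (N normal, A abnormal).  Second:
    decision (n normal, q uncertain, a abnormal).  Subscript 1 clean,
    2 noisy.
    """

    Nn1: int = 0
    Nq1: int = 0
    Na1: int = 0
    Nn2: int = 0
    Nq2: int = 0
    Na2: int = 0
    An1: int = 0
    Aq1: int = 0
    Aa1: int = 0
    An2: int = 0
    Aq2: int = 0
    Aa2: int = 0

    def __post_init__(self) -> None:
        for cell in _CELLS:
            if getattr(self, cell) < 0:
                raise ValueError(f"negative count in cell {cell}")

    @property
    def total(self) -> int:
        return sum(getattr(self, c) for c in _CELLS)


@dataclass(frozen=True)
class Weights:
    """Per-quality class weights; each pair sums to 1."""

    wa1: float
    wa2: float
    wn1: float
    wn2: float


@dataclass
class ScoreReport:
    """Weighted modified sensitivity/specificity and their mean."""

    weights: Weights
    se: float
    sp: float
    overall: float

    def __str__(self) -> str:
        return f"Se={self.se:.4f} Sp={self.sp:.4f} Overall={self.overall:.4f}"


def tally(references: pd.DataFrame, decisions: list[Decision]) -> ConfusionCounts:
    """Count decisions against reference labels.

    *references* is indexed by record_id with columns ``diagnosis``
    (+1/-1) and ``quality`` (1/0); every reference record must receive
    exactly one decision.
    """
    ids = [d.record_id for d in decisions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in decisions")
    missing = set(references.index) - set(ids)
    extra = set(ids) - set(references.index)
    if missing or extra:
        raise ValueError(
            f"decision/reference mismatch: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
        )
    counts = ConfusionCounts()
    dec_col = {-1: "n", 0: "q", 1: "a"}
    for d in decisions:
        ref = references.loc[d.record_id]
        prefix = "A" if int(ref["diagnosis"]) == 1 else "N"
        suffix = "1" if int(ref["quality"]) == 1 else "2"
        cell = f"{prefix}{dec_col[int(d.label)]}{suffix}"
        setattr(counts, cell, getattr(counts, cell) + 1)
    return counts


def compute_weights(references: pd.DataFrame) -> Weights:
    """Quality-proportion weights from a reference cohort."""
    diag = references["diagnosis"].astype(int)
    qual = references["quality"].astype(int)
    n_abn = int((diag == 1).sum())
    n_nor = int((diag == -1).sum())
    if n_abn == 0 or n_nor == 0:
        raise ValueError("both a normal and an abnormal class are required for weights")
    wa1 = int(((diag == 1) & (qual == 1)).sum()) / n_abn
    wn1 = int(((diag == -1) & (qual == 1)).sum()) / n_nor
    return Weights(wa1=wa1, wa2=1.0 - wa1, wn1=wn1, wn2=1.0 - wn1)


def _term(numer: float, denom: float, name: str, weight: float) -> float:
    if denom == 0:
        if weight != 0:
            logger.warning("zero denominator in score term %s; contributing 0", name)
        return 0.0
    return numer / denom


def score(counts: ConfusionCounts, weights: Weights) -> ScoreReport:
    """Weighted modified Se/Sp and the overall score.

    Uncertain decisions count as correct for noisy records (the Aq2/Nq2
    terms sit in the numerators) and as incorrect for clean ones.
    """
    c = counts
    se = weights.wa1 * _term(
        c.Aa1, c.Aa1 + c.Aq1 + c.An1, "Se clean", weights.wa1
    ) + weights.wa2 * _term(c.Aa2 + c.Aq2, c.Aa2 + c.Aq2 + c.An2, "Se noisy", weights.wa2)
    sp = weights.wn1 * _term(
        c.Nn1, c.Na1 + c.Nq1 + c.Nn1, "Sp clean", weights.wn1
    ) + weights.wn2 * _term(c.Nn2 + c.Nq2, c.Na2 + c.Nq2 + c.Nn2, "Sp noisy", weights.wn2)
    return ScoreReport(weights=weights, se=se, sp=sp, overall=(se + sp) / 2.0)


# ---------------------------------------------------------------------------
# correlation ranking
# ---------------------------------------------------------------------------


@dataclass
class RankingReport:
    """Per-feature label correlations and domain membership in the top k.

    ``table`` has columns feature, domain, cc, abs_cc, rank, sorted by
    decreasing |cc| with ties broken by canonical order; constant features
    have undefined correlation and rank last.
    """

    table: pd.DataFrame
    domain_counts: pd.DataFrame  # rows: domains; columns: top_10 .. top_300

    @property
    def top_feature(self) -> str:
        return str(self.table["feature"].iloc[0])

    @property
    def top_cc(self) -> float:
        return float(self.table["cc"].iloc[0])


def rank_features(
    features: FeatureTable, labels, method: str = "pearson", top_ks=(10, 100, 200, 300)
) -> RankingReport:
    """Correlate each feature with the label and rank by absolute value.

    Missing values are excluded pairwise.  The report keeps the signed
    correlation; ranking uses |cc|.
    """
    from .features import domain_of_feature

    y = np.asarray(labels, dtype=np.float64)
    X = features.values
    if X.shape[0] < 3:
        raise ValueError("at least 3 records are required for correlation ranking")
    n_feat = X.shape[1]
    ccs = np.full(n_feat, np.nan)
    if method == "spearman":
        from scipy.stats import rankdata

        y_r = rankdata(y)
    for j in range(n_feat):
        col = X[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 3:
            continue
        cj, yj = col[ok], y[ok]
        if np.std(cj) == 0 or np.std(yj) == 0:
            continue
        if method == "pearson":
            ccs[j] = float(np.corrcoef(cj, yj)[0, 1])
        elif method == "spearman":
            ccs[j] = float(np.corrcoef(rankdata(cj), rankdata(y_r[ok]))[0, 1])
        else:
            raise ValueError(f"unknown correlation method {method!r}")

    if features.domains:
        domains = list(features.domains)
    else:
        try:
            domains = [domain_of_feature(n) for n in features.feature_names]
        except KeyError:
            domains = ["unknown"] * n_feat

    abs_cc = np.abs(ccs)
    sort_key = np.where(np.isnan(abs_cc), -1.0, abs_cc)
    order = np.lexsort((np.arange(n_feat), -sort_key))  # ties: canonical order
    table = pd.DataFrame(
        {
            "feature": [features.feature_names[i] for i in order],
            "domain": [domains[i] for i in order],
            "cc": ccs[order],
            "abs_cc": abs_cc[order],
            "rank": np.arange(1, n_feat + 1),
        }
    )
    uniq_domains = list(dict.fromkeys(domains))
    counts = {}
    for k in top_ks:
        head = table.head(k)
        counts[f"top_{k}"] = [int((head["domain"] == d).sum()) for d in uniq_domains]
    domain_counts = pd.DataFrame(counts, index=uniq_domains)
    return RankingReport(table=table, domain_counts=domain_counts)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------


@dataclass
class ScoreSummary:
    """Mean +/- SD of Se, Sp and overall over repeats or folds."""

    se_mean: float
    se_sd: float
    sp_mean: float
    sp_sd: float
    overall_mean: float
    overall_sd: float
    n_runs: int

    def __str__(self) -> str:
        return (
            f"Se {self.se_mean:.2f}±{self.se_sd:.2f}  "
            f"Sp {self.sp_mean:.2f}±{self.sp_sd:.2f}  "
            f"Overall {self.overall_mean:.2f}±{self.overall_sd:.2f}"
        )


def _summarize(reports: list[ScoreReport]) -> ScoreSummary:
    se = np.array([r.se for r in reports])
    sp = np.array([r.sp for r in reports])
    ov = np.array([r.overall for r in reports])
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0  # noqa: E731
    return ScoreSummary(
        se_mean=float(np.mean(se)),
        se_sd=sd(se),
        sp_mean=float(np.mean(sp)),
        sp_sd=sd(sp),
        overall_mean=float(np.mean(ov)),
        overall_sd=sd(ov),
        n_runs=len(reports),
    )


def _subset_table(table: FeatureTable, names: list[str]) -> FeatureTable:
    idx = [table.feature_names.index(n) for n in names]
    return FeatureTable(
        record_ids=table.record_ids,
        feature_names=names,
        values=table.values[:, idx],
        domains=[table.domains[i] for i in idx] if table.domains else [],
    )


def _rows(table: FeatureTable, row_idx: np.ndarray) -> FeatureTable:
    return FeatureTable(
        record_ids=[table.record_ids[i] for i in row_idx],
        feature_names=table.feature_names,
        values=table.values[row_idx],
        domains=table.domains,
    )


def _fit_and_decide(
    table: FeatureTable,
    references: pd.DataFrame,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: SvmConfig,
    tau: float,
) -> list[Decision]:
    """Train quality+diagnosis SVMs on train rows, decide the test rows."""
    train = _rows(table, train_idx)
    test = _rows(table, test_idx)
    refs_train = references.loc[train.record_ids]
    diag_res = PcgSvm(train, refs_train["diagnosis"].to_numpy(int), config).fit()
    qual_labels = refs_train["quality"].to_numpy(int)
    if len(np.unique(qual_labels)) >= 2:
        qual_res = PcgSvm(train, qual_labels, config).fit()
        return classify_records(qual_res, diag_res, test, tau=tau)
    # single-quality training split: fall back to all-clean predictions
    margins = diag_res.decision_function(test)
    labels = diag_res.predict(test)
    return [
        Decision(record_id=r, label=int(l), quality=1, margin=float(m))
        for r, l, m in zip(test.record_ids, labels, margins)
    ]


def run_split_experiment(
    table: FeatureTable,
    references: pd.DataFrame,
    train_fraction: float,
    repeats: int = 200,
    feature_subset: list[str] | None = None,
    config: SvmConfig | None = None,
    seed: int = 0,
    tau: float = 0.3,
    full_cohort_weights: bool = False,
) -> ScoreSummary:
    """Repeated stratified random-split evaluation.

    Per repeat, ``train_fraction`` of the normal and of the abnormal
    records are sampled (separately, without overlap with the test side),
    the quality and diagnosis models are trained, and the test side is
    scored.  ``train_fraction=1`` is the memorization protocol: the model
    is trained and tested on the full cohort in a single run.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    config = config if config is not None else SvmConfig()
    if feature_subset is not None:
        table = _subset_table(table, feature_subset)
    refs = references.loc[table.record_ids]
    diag = refs["diagnosis"].to_numpy(int)
    reports: list[ScoreReport] = []

    if train_fraction == 1.0:
        idx = np.arange(len(table.record_ids))
        decisions = _fit_and_decide(table, refs, idx, idx, config, tau)
        w = compute_weights(refs)
        reports.append(score(tally(refs, decisions), w))
        return _summarize(reports)

    for rep in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, rep))
        for _attempt in range(20):
            train_idx: list[int] = []
            for cls in (-1, 1):
                cls_idx = np.nonzero(diag == cls)[0]
                n_train = max(1, int(round(train_fraction * len(cls_idx))))
                n_train = min(n_train, len(cls_idx) - 1)
                train_idx += rng.choice(cls_idx, size=n_train, replace=False).tolist()
            train_arr = np.array(sorted(train_idx))
            test_arr = np.setdiff1d(np.arange(len(diag)), train_arr)
            if len(np.unique(diag[train_arr])) >= 2 and len(np.unique(diag[test_arr])) >= 2:
                break
            logger.info("resampling split: a side had a single class")
        decisions = _fit_and_decide(table, refs, train_arr, test_arr, config, tau)
        test_refs = refs.iloc[test_arr]
        w = compute_weights(refs if full_cohort_weights else test_refs)
        reports.append(score(tally(test_refs, decisions), w))
    return _summarize(reports)


def run_domain_experiment(
    table: FeatureTable,
    references: pd.DataFrame,
    domain: str,
    folds: int = 10,
    config: SvmConfig | None = None,
    seed: int = 0,
    tau: float = 0.3,
) -> ScoreSummary:
    """Stratified k-fold cross-validation using one feature domain only.

    Every record is tested exactly once; scores are summarized over folds.
    ``domain='all'`` uses the full feature set.
    """
    from .features import DOMAINS

    if domain != "all" and domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; choose from {DOMAINS} or 'all'")
    config = config if config is not None else SvmConfig()
    if domain != "all":
        names = [n for n, d in zip(table.feature_names, table.domains) if d == domain]
        if not names:
            raise ValueError(f"feature table carries no {domain!r} columns")
        table = _subset_table(table, names)
    refs = references.loc[table.record_ids]
    diag = refs["diagnosis"].to_numpy(int)

    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=derive_seed(seed, 0))
    reports = []
    for train_idx, test_idx in skf.split(np.zeros(len(diag)), diag):
        decisions = _fit_and_decide(table, refs, train_idx, test_idx, config, tau)
        test_refs = refs.iloc[test_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = compute_weights(test_refs)
        reports.append(score(tally(test_refs, decisions), w))
    return _summarize(reports)
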