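"""Experimental protocol: repeated cross-validation, metrics, tuning and
the variance-corrected paired t-test.

Ten repetitions of ten-fold cross-validation give 100 paired fold values
per pipeline.  Folds are drawn either over sentences or over whole
abstracts (no abstract ever split across train and test).  The Gaussian
kernel parameter is tuned on a power-of-ten grid by inner cross-
validation, ties broken toward the smaller value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import corpus as corpus_mod
from . import kernels as kernel_mod
from . import pmkl as pmkl_mod
from . import semantic as semantic_mod
from ._stopwords import DEFAULT_STOP_WORDS, stop_list_hash

THETA_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class CVPlan:
    k: int = 10
    r: int = 10
    scheme: str = "sentence"  # or "abstract"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise EvaluationError(f"need k >= 2 folds, got {self.k}")
        if self.r < 1:
            raise EvaluationError(f"need r >= 1 repetitions, got {self.r}")
        if self.scheme not in ("sentence", "abstract"):
            raise EvaluationError(f"unknown randomisation scheme {self.scheme!r}")


def make_folds(
    sample_ids: list[str],
    abstract_ids: list[str] | None,
    plan: CVPlan,
) -> list[list[np.ndarray]]:
    """Test-fold index arrays, ``folds[rep][fold]``.

    Sentence scheme: shuffle sentences, cut into k near-equal parts
    (sizes differ by at most one sentence).  Abstract scheme: shuffle
    abstracts, cut the abstract list into k near-equal parts; every
    sentence follows its abstract.
    """
    n = len(sample_ids)
    out: list[list[np.ndarray]] = []
    if plan.scheme == "abstract":
        if abstract_ids is None:
            raise EvaluationError("abstract scheme requires abstract_ids")
        uniq = sorted(set(abstract_ids))
        if plan.k > len(uniq):
            raise EvaluationError(
                f"k={plan.k} folds but only {len(uniq)} abstracts"
            )
        by_abstract: dict[str, list[int]] = {a: [] for a in uniq}
        for i, a in enumerate(abstract_ids):
            by_abstract[a].append(i)
    elif plan.k > n:
        raise EvaluationError(f"k={plan.k} folds but only {n} samples")

    for rep in range(plan.r):
        rng = np.random.default_rng([plan.seed, rep])
        if plan.scheme == "sentence":
            perm = rng.permutation(n)
            rep_folds = [np.sort(part) for part in np.array_split(perm, plan.k)]
        else:
            order = rng.permutation(len(uniq))
            rep_folds = []
            for part in np.array_split(order, plan.k):
                idx = np.concatenate([by_abstract[uniq[j]] for j in part])
                rep_folds.append(np.sort(idx))
        out.append(rep_folds)
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricSet:
    precision: float
    recall: float
    f_score: float
    error_pct: float
    auc: float | None


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with half credit for tied scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC undefined for a single-class fold")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def compute_metrics(
    labels, scores, threshold: float = 0.5
) -> MetricSet:
    """Confusion-matrix metrics at ``threshold`` plus rank AUC.

    A single-class fold has no defined AUC; it is reported as ``None``
    with a warning so aggregation can exclude it.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise EvaluationError("labels and scores length mismatch")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_score = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    error_pct = 100.0 * float(np.mean(pred != labels))
    try:
        auc = auc_score(labels, scores)
    except EvaluationError:
        warnings.warn("single-class test fold: AUC reported as missing")
        auc = None
    return MetricSet(precision, recall, f_score, error_pct, auc)


def corrected_ttest(
    metric_a,
    metric_b,
    k: int = 10,
    r: int = 10,
    test_fraction: float | None = None,
) -> tuple[float, float]:
    """Corrected resampled paired t-test over k*r fold values.

    t = mean(d) / sqrt(var(d) * (1/(k r) + n2/n1)) with n2/n1 the
    test/train size ratio; two-sided p on k*r - 1 degrees of freedom.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise EvaluationError("paired fold vectors must share 1-D shape")
    n = len(a)
    if n != k * r:
        raise EvaluationError(f"expected {k * r} paired values, got {n}")
    if test_fraction is None:
        test_fraction = 1.0 / k
    ratio = test_fraction / (1.0 - test_fraction)
    d = a - b
    mean = float(np.mean(d))
    var = float(np.var(d, ddof=1)) if n > 1 else 0.0
    if var <= (1e-12 * max(1.0, abs(mean))) ** 2:  # degenerate variance
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / np.sqrt(var * (1.0 / (k * r) + ratio))
    p = 2.0 * float(stats.t.sf(abs(t), df=k * r - 1))
    return float(t), p


# ---------------------------------------------------------------------------
# inner tuning
# ---------------------------------------------------------------------------


def _fit_predict_auc(
    blocks: list[np.ndarray],
    kinds: list[str],
    params: list[dict],
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    beta,
    criterion: str,
    max_iter: int = 30,
) -> float | None:
    train_Ks, test_Ks = [], []
    for block, kind, par in zip(blocks, kinds, params):
        train_Ks.append(
            kernel_mod.make_kernel(kind, block[train_idx], **par).K
        )
        test_Ks.append(
            kernel_mod.make_kernel(kind, block[test_idx], block[train_idx], **par).K
        )
    model = pmkl_mod.fit(train_Ks, labels[train_idx], mode="fixed",
                         fixed_beta=beta, max_iter=max_iter)
    pred = pmkl_mod.predict(model, test_Ks)
    ms = compute_metrics(labels[test_idx], pred.scores)
    return ms.auc if criterion == "auc" else ms.f_score


def tune_gaussian_theta(
    blocks: list[np.ndarray],
    kinds: list[str],
    base_params: list[dict],
    labels,
    grid=THETA_GRID,
    inner_plan: CVPlan | None = None,
    beta=None,
    criterion: str = "auc",
) -> float:
    """Pick the shared Gaussian parameter maximising mean inner-fold AUC
    (or F-score); exact ties go to the smaller theta."""
    grid = sorted(grid)
    if len(grid) == 1:
        return float(grid[0])
    labels = np.asarray(labels)
    if inner_plan is None:
        inner_plan = CVPlan(k=3, r=1, scheme="sentence", seed=0)
    folds = make_folds([str(i) for i in range(len(labels))], None, inner_plan)
    all_idx = np.arange(len(labels))
    best_theta, best_score = float(grid[0]), -np.inf
    for theta in grid:
        params = [
            {**p, "theta": theta} if kind == "gaussian" else p
            for kind, p in zip(kinds, base_params)
        ]
        scores = []
        for rep_folds in folds:
            for test_idx in rep_folds:
                train_idx = np.setdiff1d(all_idx, test_idx)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    s = _fit_predict_auc(
                        blocks, kinds, params, labels, train_idx, test_idx,
                        beta, criterion,
                    )
                if s is not None:
                    scores.append(s)
        mean_score = float(np.mean(scores)) if scores else -np.inf
        if mean_score > best_score + 1e-12:
            best_score, best_theta = mean_score, float(theta)
    return best_theta


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


@dataclass
class FoldRecord:
    pipeline: str
    repetition: int
    fold: int
    theta: float | None
    metrics: MetricSet


@dataclass
class ResultRow:
    pipeline: str
    n_folds: int
    mean: dict = field(default_factory=dict)
    se_folds: dict = field(default_factory=dict)
    se_reps: dict = field(default_factory=dict)


_METRIC_NAMES = ("f_score", "error_pct", "precision", "recall", "auc")


def summarize_folds(records: list[FoldRecord], r: int) -> ResultRow:
    """Mean with two standard errors: over all folds and over the r
    repetition means (both conventions are reported)."""
    row = ResultRow(pipeline=records[0].pipeline, n_folds=len(records))
    for name in _METRIC_NAMES:
        vals = np.array(
            [getattr(rec.metrics, name) for rec in records
             if getattr(rec.metrics, name) is not None],
            dtype=np.float64,
        )
        if len(vals) == 0:
            continue
        row.mean[name] = float(vals.mean())
        row.se_folds[name] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rep_means = []
        for rep in sorted({rec.repetition for rec in records}):
            rv = [
                getattr(rec.metrics, name)
                for rec in records
                if rec.repetition == rep and getattr(rec.metrics, name) is not None
            ]
            if rv:
                rep_means.append(float(np.mean(rv)))
        rep_means = np.asarray(rep_means)
        row.se_reps[name] = (
            float(rep_means.std(ddof=1) / np.sqrt(len(rep_means)))
            if len(rep_means) > 1
            else 0.0
        )
    return row


def _validate_config(config: dict) -> None:
    if "pipelines" not in config or not config["pipelines"]:
        raise EvaluationError("config must name at least one pipeline")
    smoother_names = set((config.get("smoothers") or {}).keys())
    for pipe in config["pipelines"]:
        if "name" not in pipe or "kernels" not in pipe or not pipe["kernels"]:
            raise EvaluationError("each pipeline needs a name and kernels")
        for kspec in pipe["kernels"]:
            kind = kspec.get("kind")
            if kind not in kernel_mod.KERNEL_KINDS:
                raise EvaluationError(f"unknown kernel kind {kind!r}")
            sm = kspec.get("smoother")
            if sm is not None and sm not in smoother_names:
                raise EvaluationError(f"pipeline references unknown smoother {sm!r}")
    for name, sm in (config.get("smoothers") or {}).items():
        if sm.get("model") not in ("hal", "hal_distance", "beagle", "identity"):
            raise EvaluationError(f"smoother {name!r} has unknown model")


def _build_smoothers(
    config: dict,
    unlabeled_tokens: list[list[str]],
    vocab: corpus_mod.Vocabulary,
    seed: int,
) -> dict[str, object]:
    out: dict[str, object] = {}
    hal_cache: dict[tuple[int, bool], semantic_mod.HALMatrix] = {}
    for name, spec in (config.get("smoothers") or {}).items():
        model = spec["model"]
        if model == "identity":
            out[name] = None
        elif model in ("hal", "hal_distance"):
            L = int(spec.get("L", 3))
            key = (L, model == "hal_distance")
            if key not in hal_cache:
                hal_cache[key] = semantic_mod.build_hal(
                    unlabeled_tokens, vocab, L, keep_components=key[1]
                )
            h = hal_cache[key]
            if model == "hal":
                out[name] = semantic_mod.combine_hal(h)
            else:
                out[name] = semantic_mod.hal_distance_matrix(h, int(spec["l"]))
        elif model == "beagle":
            b = semantic_mod.build_beagle(
                unlabeled_tokens,
                vocab,
                D=int(spec.get("D", 4096)),
                seed=int(spec.get("seed", seed)),
                max_basis=spec.get("max_basis"),
            )
            out[name] = b.B
    return out


def run_experiment(config: dict) -> dict:
    """Run the full protocol described by ``config``.

    The config either points at corpus files (``labeled: {path, dialect}``,
    ``unlabeled: {path}``) or carries in-memory inputs
    (``labeled_sentences``, ``unlabeled_tokens``).  Deterministic given
    the master ``seed``.
    """
    _validate_config(config)
    seed = int(config.get("seed", 0))
    stop_words = DEFAULT_STOP_WORDS

    if "labeled_sentences" in config:
        sentences = config["labeled_sentences"]
    else:
        lab = config["labeled"]
        sentences = corpus_mod.read_labeled_corpus(
            lab["path"], lab.get("dialect", "inline-tag")
        )
    token_seqs = [corpus_mod.preprocess(s, stop_words) for s in sentences]
    vocab = corpus_mod.build_vocabulary(token_seqs)
    dtm = corpus_mod.vectorize(
        token_seqs, vocab, [s.sentence_id for s in sentences]
    )
    labels = np.array([s.label for s in sentences])
    abstract_ids = [s.abstract_id for s in sentences]

    unlabeled_tokens: list[list[str]] = []
    if "unlabeled_tokens" in config:
        raw = config["unlabeled_tokens"]
    elif "unlabeled" in config:
        raw = corpus_mod.read_unlabeled_corpus(config["unlabeled"]["path"])
    else:
        raw = []
    unlabeled_tokens = [
        corpus_mod.tokenize(" ".join(seq), stop_words) for seq in raw
    ]

    smoothers = _build_smoothers(config, unlabeled_tokens, vocab, seed)
    epsilon = float((config.get("smoothing") or {}).get("epsilon", 0.01))

    # smooth the full matrix once per smoother: S comes from unlabelled
    # text only, so it is identical for every fold
    blocks_by_smoother: dict[str | None, np.ndarray] = {
        None: kernel_mod.smooth(dtm.X, None, 0.0).XS
    }
    for name, S in smoothers.items():
        blocks_by_smoother[name] = kernel_mod.smooth(dtm.X, S, epsilon).XS

    cv_cfg = config.get("cv") or {}
    plan = CVPlan(
        k=int(cv_cfg.get("k", 10)),
        r=int(cv_cfg.get("r", 10)),
        scheme=cv_cfg.get("scheme", "sentence"),
        seed=seed,
    )
    folds = make_folds(
        [s.sentence_id for s in sentences], abstract_ids, plan
    )
    tuning = config.get("tuning") or {}
    # default follows the randomisation scheme: per-fold tuning with the
    # abstract split, one global parameter with the sentence split
    default_mode = "per-fold" if plan.scheme == "abstract" else "global"
    tune_mode = tuning.get("mode", default_mode)  # per-fold | global | none
    grid = tuple(tuning.get("grid", THETA_GRID))
    criterion = tuning.get("criterion", "auc")
    classifier_cfg = config.get("classifier") or {}
    max_iter = int(classifier_cfg.get("max_iter", 40))

    all_records: dict[str, list[FoldRecord]] = {}
    rows: list[ResultRow] = []
    all_idx = np.arange(len(sentences))

    for pipe in config["pipelines"]:
        name = pipe["name"]
        kinds = [k["kind"] for k in pipe["kernels"]]
        blocks = [blocks_by_smoother[k.get("smoother")] for k in pipe["kernels"]]
        base_params = []
        needs_tuning = False
        for kspec in pipe["kernels"]:
            par: dict = {}
            if kspec["kind"] == "gaussian":
                theta = kspec.get("theta", "tune")
                if theta == "tune":
                    needs_tuning = tune_mode != "none"
                    par["theta"] = 0.1  # fallback when tuning disabled
                else:
                    par["theta"] = float(theta)
            elif kspec["kind"] == "polynomial":
                par["degree"] = int(kspec.get("degree", 2))
            base_params.append(par)
        beta = pipe.get("beta")
        mode = pipe.get("mode", "fixed")

        global_theta: float | None = None
        if needs_tuning and tune_mode == "global":
            global_theta = tune_gaussian_theta(
                blocks, kinds, base_params, labels, grid=grid,
                inner_plan=CVPlan(k=int(tuning.get("inner_k", 3)), r=1, seed=seed),
                beta=beta, criterion=criterion,
            )

        records: list[FoldRecord] = []
        for rep, rep_folds in enumerate(folds):
            for f, test_idx in enumerate(rep_folds):
                train_idx = np.setdiff1d(all_idx, test_idx)
                theta_used: float | None = None
                params = base_params
                if needs_tuning:
                    if tune_mode == "per-fold":
                        theta_used = tune_gaussian_theta(
                            [b[train_idx] for b in blocks], kinds, base_params,
                            labels[train_idx], grid=grid,
                            inner_plan=CVPlan(
                                k=int(tuning.get("inner_k", 3)), r=1,
                                seed=seed * 1000 + rep * plan.k + f,
                            ),
                            beta=beta, criterion=criterion,
                        )
                    else:
                        theta_used = global_theta
                    params = [
                        {**p, "theta": theta_used} if kind == "gaussian" else p
                        for kind, p in zip(kinds, base_params)
                    ]
                train_Ks = [
                    kernel_mod.make_kernel(kind, b[train_idx], **par).K
                    for b, kind, par in zip(blocks, kinds, params)
                ]
                test_Ks = [
                    kernel_mod.make_kernel(kind, b[test_idx], b[train_idx], **par).K
                    for b, kind, par in zip(blocks, kinds, params)
                ]
                model = pmkl_mod.fit(
                    train_Ks, labels[train_idx], mode=mode, fixed_beta=beta,
                    max_iter=max_iter, seed=seed,
                )
                pred = pmkl_mod.predict(model, test_Ks)
                ms = compute_metrics(labels[test_idx], pred.scores)
                records.append(FoldRecord(name, rep, f, theta_used, ms))
        all_records[name] = records
        rows.append(summarize_folds(records, plan.r))

    return {
        "rows": rows,
        "fold_records": all_records,
        "provenance": {
            "seed": seed,
            "stop_list_hash": stop_list_hash(stop_words),
            "n_features": len(vocab),
            "n_sentences": len(sentences),
            "cv": {"k": plan.k, "r": plan.r, "scheme": plan.scheme},
            "theta_per_fold": {
                name: [rec.theta for rec in recs]
                for name, recs in all_records.items()
            },
        },
    }
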