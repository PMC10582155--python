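"""Designed experiments and performance evaluation.

Two experiment families tune the method:

* a **full factorial** over the band-limited sample-entropy quadruple
  (F_L, F_H, m, r) — 3 x 9 x 9 x 5 = 1215 runs on the study grid — each
  run scored by a simple entropy-threshold classifier;
* a **2^(5-1) fractional factorial** (resolution V, defining relation
  I = ABCDE) over the five two-level model factors A-E, analysed by
  main-effect estimation on coded +/-1 columns (effect = mean response
  at +1 minus mean at -1; coefficient = effect / 2) with t/p values
  from the usual regression on the coded design.

Classifier performance is summarized by sensitivity, specificity,
accuracy, precision and F1, each with a standard error over repeated
patient-level train/test splits.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ModelConfig, predict, train
from .features import SampEnParams
from .pipeline import CycleDataset, stratified_patient_split
from .preprocess import CardiacCycle

#: The study grid for the entropy-parameter search (1215 combinations).
SAMPEN_GRID: dict[str, list] = {
    "F_L": [10, 50, 100],
    "F_H": [200, 300, 400, 500, 600, 700, 800, 900, 1000],
    "m": [2, 3, 4, 5, 6, 7, 8, 9, 10],
    "r": [0.1, 0.2, 0.3, 0.4, 0.5],
}


@dataclass
class DOEDesign:
    factor_names: list[str]
    levels: dict[str, list]
    runs: pd.DataFrame
    design_type: str
    defining_relation: str = ""

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def full_factorial(levels: dict[str, list]) -> DOEDesign:
    """Cartesian-product enumeration of all level combinations, in
    lexicographic order of the given factor/level ordering."""
    if not levels:
        raise ValueError("need at least one factor")
    for name, lv in levels.items():
        if len(lv) < 1:
            raise ValueError(f"factor {name!r} has no levels")
    names = list(levels)
    rows = list(itertools.product(*(levels[n] for n in names)))
    return DOEDesign(
        factor_names=names,
        levels=dict(levels),
        runs=pd.DataFrame(rows, columns=names),
        design_type="full_factorial",
    )


def fractional_factorial_2k1(k: int = 5, factor_names: list[str] | None = None) -> DOEDesign:
    """Half-fraction two-level design: 2^(k-1) runs.

    The first k-1 columns form a full two-level factorial; the k-th
    column is their elementwise product, i.e. the defining relation
    I = (product of all factors). For k = 5 this is the resolution-V
    design whose main effects alias only four-factor interactions.
    """
    if k < 3:
        raise ValueError("need k >= 3 for a useful half fraction")
    names = factor_names or [chr(ord("A") + i) for i in range(k)]
    if len(names) != k:
        raise ValueError(f"expected {k} factor names, got {len(names)}")
    base = np.array(list(itertools.product([-1, 1], repeat=k - 1)))
    gen = base.prod(axis=1)
    runs = pd.DataFrame(np.column_stack([base, gen]), columns=names)
    return DOEDesign(
        factor_names=names,
        levels={n: [-1, 1] for n in names},
        runs=runs,
        design_type="fractional_2k1",
        defining_relation="I=" + "".join(names),
    )


@dataclass
class EffectTable:
    """Per-term effect, coefficient (= effect/2), t and p values."""

    table: pd.DataFrame  # columns: term, effect, coef, t_value, p_value

    def __getitem__(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def estimate_effects(
    design: DOEDesign,
    responses: np.ndarray,
    replicates: int = 1,
    interactions: list[tuple[str, str]] | None = None,
) -> EffectTable:
    """Main effects (and requested two-factor interactions) of a
    two-level coded design.

    ``responses`` is the run-ordered response vector, repeated whole-
    design blocks when ``replicates`` > 1. The effect of a term is the
    mean response at its +1 level minus the mean at -1; its regression
    coefficient is exactly half the effect. t and p come from ordinary
    least squares on the coded columns with the residual (replicate)
    degrees of freedom; with zero residual variance t/p are undefined
    and reported as NaN.
    """
    if interactions is None:
        interactions = [("B", "D")] if {"B", "D"} <= set(design.factor_names) else []
    y = np.asarray(responses, dtype=np.float64).ravel()
    n_runs = design.n_runs
    if y.size != n_runs * replicates:
        raise ValueError(
            f"expected {n_runs * replicates} responses ({n_runs} runs x "
            f"{replicates} replicates), got {y.size}"
        )
    coded = design.runs[design.factor_names].to_numpy(dtype=np.float64)
    if not np.all(np.isin(coded, (-1.0, 1.0))):
        raise ValueError("effect estimation requires coded +/-1 factor columns")
    terms = list(design.factor_names)
    cols = [coded[:, i] for i in range(coded.shape[1])]
    for a, b in interactions:
        ia, ib = design.factor_names.index(a), design.factor_names.index(b)
        terms.append(f"{a}*{b}")
        cols.append(coded[:, ia] * coded[:, ib])
    X1 = np.column_stack([np.ones(n_runs)] + cols)
    X = np.tile(X1, (replicates, 1))
    nobs, p = X.shape
    df_resid = nobs - p
    if df_resid <= 0:
        raise ValueError("no error degrees of freedom: add replicates or drop terms")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    if ssr <= 1e-20 * max(1.0, float(y @ y)):  # numerically exact fit
        ssr = 0.0
    sigma2 = ssr / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    pvals = np.where(np.isnan(tvals), np.nan,
                     2.0 * stats.t.sf(np.abs(np.nan_to_num(tvals)), df_resid))
    rows = []
    for i, term in enumerate(terms, start=1):
        rows.append({
            "term": term,
            "effect": 2.0 * beta[i],
            "coef": beta[i],
            "t_value": tvals[i],
            "p_value": pvals[i],
        })
    return EffectTable(table=pd.DataFrame(rows))


@dataclass
class Metrics:
    """The five performance measures with their standard errors.

    Undefined ratios (zero denominators) are None, never 0.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    f1: float | None
    se_sensitivity: float | None = None
    se_specificity: float | None = None
    se_accuracy: float | None = None
    se_precision: float | None = None
    se_f1: float | None = None
    n_repeats: int = 1

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision, "f1": self.f1,
        }


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    """Sensitivity, specificity, accuracy, precision and F1 from a
    binary confusion matrix (positive class = stenosis)."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    sen = tp / (tp + fn) if (tp + fn) > 0 else None
    spe = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / total
    pre = tp / (tp + fp) if (tp + fp) > 0 else None
    f1 = (2 * pre * sen / (pre + sen)
          if pre is not None and sen is not None and (pre + sen) > 0 else None)
    return Metrics(sensitivity=sen, specificity=spe, accuracy=acc, precision=pre, f1=f1)


_METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision", "f1")


def summarize_repeats(per_repeat: list[Metrics]) -> Metrics:
    """Mean and SE (= sample sd / sqrt(n)) of each metric across
    repeats; repeats where a metric is undefined are dropped for that
    metric."""
    n = len(per_repeat)
    out: dict = {"n_repeats": n}
    for name in _METRIC_NAMES:
        vals = [getattr(m, name) for m in per_repeat if getattr(m, name) is not None]
        if not vals:
            out[name] = None
            out[f"se_{name}"] = None
            continue
        arr = np.array(vals, dtype=np.float64)
        out[name] = float(arr.mean())
        out[f"se_{name}"] = (float(arr.std(ddof=1) / math.sqrt(len(arr)))
                             if len(arr) > 1 else 0.0)
    return Metrics(**out)


def evaluate_split(ds: CycleDataset, cfg: ModelConfig, split_seed: int,
                   test_fraction: float = 0.2) -> Metrics:
    """Train on one stratified patient-level split and score the held-out
    cycles."""
    rng = np.random.default_rng(split_seed)
    train_mask, test_mask = stratified_patient_split(ds, test_fraction, rng)
    tm = train(ds.images[train_mask], ds.features[train_mask],
               ds.labels[train_mask], cfg)
    labels, _ = predict(tm, ds.images[test_mask], ds.features[test_mask])
    truth = ds.labels[test_mask]
    tp = int(np.sum((labels == 1) & (truth == 1)))
    fp = int(np.sum((labels == 1) & (truth == 0)))
    tn = int(np.sum((labels == 0) & (truth == 0)))
    fn = int(np.sum((labels == 0) & (truth == 1)))
    return metrics_from_confusion(tp, fp, tn, fn)


def repeated_evaluation(ds: CycleDataset, cfg: ModelConfig, n_repeats: int = 10,
                        seed: int = 0, test_fraction: float = 0.2) -> Metrics:
    """Point estimates and standard errors over ``n_repeats``
    independent stratified patient-level splits (split seeds
    seed .. seed+n_repeats-1)."""
    if n_repeats < 2:
        raise ValueError("need n_repeats >= 2 to estimate a standard error")
    per_repeat = [
        evaluate_split(ds, cfg, split_seed=seed + rep, test_fraction=test_fraction)
        for rep in range(n_repeats)
    ]
    return summarize_repeats(per_repeat)


def _threshold_classify(values_train, labels_train, values_test):
    """Best accuracy-maximizing threshold (and direction) on the train
    fold, applied to the test fold. Stenosis is called when entropy is
    on the chosen side of the threshold."""
    order = np.argsort(values_train)
    v = values_train[order]
    cuts = np.concatenate([[v[0] - 1.0], (v[:-1] + v[1:]) / 2.0, [v[-1] + 1.0]])
    best = (-1.0, 0.0, 1)
    for cut in cuts:
        for direction in (1, -1):
            pred = (direction * values_train >= direction * cut).astype(int)
            acc = float(np.mean(pred == labels_train))
            if acc > best[0]:
                best = (acc, cut, direction)
    _, cut, direction = best
    return (direction * values_test >= direction * cut).astype(int)


def run_sampen_doe(
    cycles: list[CardiacCycle],
    grid: dict[str, list] | None = None,
    split_seed: int = 0,
    test_fraction: float = 0.5,
    analysis_fs: float | None = 2205.0,
) -> pd.DataFrame:
    """Score every (F_L, F_H, m, r) quadruple of the grid by a
    threshold classifier on its banded sample entropy.

    Band-passed, decimated series are cached per (F_L, F_H) band so the
    grid sweep costs one O(N^2) entropy evaluation per (m, r) pair per
    band. Grid corners with F_L >= F_H (possible in custom grids) are
    dropped. Returns a table ranked by test accuracy with columns
    rank, F_L, F_H, m, r, sensitivity, specificity, accuracy.
    """
    grid = grid or SAMPEN_GRID
    design = full_factorial(grid)
    design.runs = design.runs[design.runs["F_L"] < design.runs["F_H"]].reset_index(drop=True)
    labels = np.array([1 if c.label == "stenosis" else 0 for c in cycles])
    if len(set(labels)) < 2:
        raise ValueError("cycles must include both classes")
    rng = np.random.default_rng(split_seed)
    idx = rng.permutation(len(cycles))
    n_test = max(1, int(round(test_fraction * len(cycles))))
    test_idx, train_idx = idx[:n_test], idx[n_test:]
    if len(train_idx) == 0:
        raise ValueError("empty training fold")

    from .features import bandpass, sample_entropy

    band_cache: dict[tuple[float, float], list[np.ndarray]] = {}

    def banded_series(key: tuple[float, float]) -> list[np.ndarray]:
        if key not in band_cache:
            series = []
            for cyc in cycles:
                z = bandpass(cyc.samples, cyc.fs, key[0], key[1])
                if analysis_fs is not None:
                    q = max(1, int(cyc.fs // analysis_fs))
                    while q > 1 and cyc.fs / q <= 2.0 * key[1]:
                        q -= 1
                    z = z[::q]
                series.append(z)
            band_cache[key] = series
        return band_cache[key]

    rows = []
    for run in design.runs.itertuples(index=False):
        p = SampEnParams(run.F_L, run.F_H, int(run.m), run.r)
        cache = banded_series((p.F_L, p.F_H))
        values = np.empty(len(cycles))
        ok = np.ones(len(cycles), dtype=bool)
        for i in range(len(cycles)):
            try:
                values[i] = sample_entropy(cache[i], p.m, p.r)
            except ValueError:
                values[i] = np.nan
                ok[i] = False
        # impute undefined entropies with the mean of defined ones
        if (~ok).any() and ok.any():
            values[~ok] = values[ok].mean()
        elif not ok.any():
            rows.append({"F_L": p.F_L, "F_H": p.F_H, "m": p.m, "r": p.r,
                         "sensitivity": np.nan, "specificity": np.nan,
                         "accuracy": np.nan})
            continue
        pred = _threshold_classify(values[train_idx], labels[train_idx], values[test_idx])
        truth = labels[test_idx]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        m = metrics_from_confusion(tp, fp, tn, fn)
        rows.append({"F_L": p.F_L, "F_H": p.F_H, "m": p.m, "r": p.r,
                     "sensitivity": m.sensitivity, "specificity": m.specificity,
                     "accuracy": m.accuracy})
    table = pd.DataFrame(rows)
    table = table.sort_values("accuracy", ascending=False, kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def run_model_doe(
    datasets: "CycleDataset | dict[str, CycleDataset]",
    base_cfg: ModelConfig,
    n_repeats: int = 2,
    seed: int = 0,
) -> tuple[DOEDesign, pd.DataFrame, EffectTable]:
    """Run the 2^(5-1) screening experiment over factors A-E.

    Each of the 16 runs trains and evaluates the concatenated model at
    its factor combination, replicated ``n_repeats`` times on different
    patient-level splits; accuracy is the response. Factor C selects
    the filtering used to build the cycle dataset, so ``datasets``
    should be a dict with keys "TF" and "EMD" (a single dataset is
    accepted and then serves both levels, collapsing factor C).
    Returns the design, the per-run response table, and the effect
    table (including B*D).
    """
    if not isinstance(datasets, dict):
        datasets = {"TF": datasets, "EMD": datasets}
    if set(datasets) != {"TF", "EMD"}:
        raise ValueError("datasets must have exactly the keys 'TF' and 'EMD'")
    design = fractional_factorial_2k1(5)
    level_map = {
        "A": {-1: 2, 1: 3}, "B": {-1: 4, 1: 10}, "C": {-1: "TF", 1: "EMD"},
        "D": {-1: 2, 1: 4}, "E": {-1: 4, 1: 10},
    }
    responses = []
    rows = []
    for rep in range(n_repeats):
        for run_i, run in enumerate(design.runs.itertuples(index=False)):
            filtering = level_map["C"][run.C]
            cfg = ModelConfig(
                ann_layers=level_map["A"][run.A], ann_nodes=level_map["B"][run.B],
                filtering=filtering, head_layers=level_map["D"][run.D],
                head_nodes=level_map["E"][run.E],
                image_size_px=base_cfg.image_size_px,
                resnet_variant=base_cfg.resnet_variant, seed=base_cfg.seed + rep,
                epochs=base_cfg.epochs, batch_size=base_cfg.batch_size,
                learning_rate=base_cfg.learning_rate,
            )
            m = evaluate_split(datasets[filtering], cfg, split_seed=seed + rep)
            responses.append(m.accuracy)
            rows.append({"replicate": rep, "run": run_i, "A": run.A, "B": run.B,
                         "C": run.C, "D": run.D, "E": run.E, "accuracy": m.accuracy})
    effects = estimate_effects(design, np.array(responses), replicates=n_repeats)
    return design, pd.DataFrame(rows), effects


def aggregate_recording_votes(cycle_labels: np.ndarray, groups: np.ndarray) -> dict:
    """Majority vote of cycle-level labels per recording/group; ties go
    to stenosis."""
    out = {}
    for g in np.unique(groups):
        votes = cycle_labels[groups == g]
        out[g] = int(votes.mean() >= 0.5)
    return out
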