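"""Cross-dataset statistics: peak co-occurrence, ranked-label running-sum
enrichment, element/function cutoff sweeps, contingency associations,
knockdown expression shifts and RBP-target enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core_io import PeakSet


@dataclass
class StatResult:
    statistic: float
    p_value: float
    test_used: str
    n: int
    extra: dict | None = None


# ---------------------------------------------------------------------------
# Peak co-occurrence

def _strand_trees(peaks: PeakSet) -> dict:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for p in peaks.peaks:
        trees.setdefault((p.chrom, p.strand), IntervalTree()).addi(
            p.start, p.end)
    return trees


def _directional_fraction(a: PeakSet, b_trees: dict) -> float:
    hit = 0
    for p in a.peaks:
        tree = b_trees.get((p.chrom, p.strand))
        if tree and tree.overlap(p.start, p.end):
            hit += 1
    return hit / len(a.peaks)


def peak_overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """max(frac of A peaks hitting B, frac of B peaks hitting A);
    overlap means >= 1 shared base on the same strand."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty peak set")
    fa = _directional_fraction(a, _strand_trees(b))
    fb = _directional_fraction(b, _strand_trees(a))
    return max(fa, fb)


def overlap_matrix(peak_sets: dict, min_peaks: int = 100) -> pd.DataFrame:
    """Symmetric pairwise overlap-fraction matrix over datasets with at
    least ``min_peaks`` peaks (diagonal = 1 by self-overlap)."""
    if len(peak_sets) < 2:
        raise ValueError("need >= 2 peak sets")
    kept = {d: ps for d, ps in peak_sets.items() if len(ps) >= min_peaks}
    if len(kept) < 2:
        raise ValueError("fewer than 2 datasets survive the peak-count filter")
    ids = sorted(kept)
    trees = {d: _strand_trees(kept[d]) for d in ids}
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            f = max(_directional_fraction(kept[a], trees[b]),
                    _directional_fraction(kept[b], trees[a]))
            mat.loc[a, b] = mat.loc[b, a] = f
    return mat


# ---------------------------------------------------------------------------
# Running-sum (GSEA-style) enrichment of labeled pairs in a ranking

def _running_sum_es(is_label: np.ndarray) -> float:
    """Signed maximum deviation of the unweighted running sum:
    +1/|labels| at labeled items, -1/(n - |labels|) at the rest."""
    n = len(is_label)
    k = int(is_label.sum())
    steps = np.where(is_label, 1.0 / k, -1.0 / (n - k))
    rs = np.cumsum(steps)
    return float(rs[np.argmax(np.abs(rs))])


def running_sum_enrichment(ranked_items: list, label_set: set,
                           n_perm: int = 10_000, seed: int = 0) -> StatResult:
    """Enrichment of labeled items toward the top of a ranking.

    ``ranked_items`` is ordered by the score (e.g. overlap fraction,
    descending).  ES is the signed maximum deviation of the running
    sum; the p-value is (#permutations with ES >= observed + 1) /
    (n_perm + 1) over random label placements.
    """
    n = len(ranked_items)
    is_label = np.array([x in label_set for x in ranked_items])
    k = int(is_label.sum())
    if k == 0 or k == n:
        raise ValueError("label set must be a proper, nonempty subset")
    es = _running_sum_es(is_label)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = is_label.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _running_sum_es(perm) >= es:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return StatResult(es, p, "label_permutation", n, {"n_labeled": k})


# ---------------------------------------------------------------------------
# Element <-> function accuracy sweep

SWEEP_COLUMNS = ["cutoff", "TP", "FP", "FN", "TN", "accuracy", "f1"]


def function_accuracy_sweep(datasets: pd.DataFrame,
                            element_function: dict) -> dict:
    """Sweep relative-information cutoffs over dataset top elements.

    ``datasets`` columns: dataset_id, top_element, relinfo, functions
    (iterable of annotated function labels; empty = unannotated).
    ``element_function`` maps each element to its linked function.  At a
    cutoff c a dataset is TP if relinfo > c and its annotations include
    the function linked to its top element; FP if relinfo > c otherwise;
    FN if relinfo <= c but the dataset has any annotated function; TN if
    relinfo <= c and it has none.  Returns the sweep table plus the
    accuracy- and F1-maximizing cutoffs (ties to the smallest).
    """
    if not element_function:
        raise ValueError("empty annotation table")
    rel = datasets["relinfo"].to_numpy(dtype=float)
    matches = np.array([
        element_function.get(row.top_element) in set(row.functions)
        for row in datasets.itertuples(index=False)])
    annotated = np.array([len(set(row.functions)) > 0
                          for row in datasets.itertuples(index=False)])
    rows = []
    for cutoff in sorted(set(rel)):
        above = rel > cutoff
        tp = int((above & matches).sum())
        fp = int((above & ~matches).sum())
        fn = int((~above & annotated).sum())
        tn = int((~above & ~annotated).sum())
        acc = (tp + tn) / (tp + tn + fp + fn)
        f1 = (2 * tp) / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        rows.append({"cutoff": cutoff, "TP": tp, "FP": fp, "FN": fn,
                     "TN": tn, "accuracy": acc, "f1": f1})
    sweep = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    best_acc = sweep.loc[sweep["accuracy"].idxmax(), "cutoff"]
    best_f1 = sweep.loc[sweep["f1"].idxmax(), "cutoff"]
    return {"sweep": sweep, "best_accuracy_cutoff": float(best_acc),
            "best_f1_cutoff": float(best_f1)}


# ---------------------------------------------------------------------------
# 2x2 contingency association

def contingency_association(membership_a, membership_b) -> StatResult:
    """Odds ratio and significance for two binary labelings of a universe.

    The odds ratio is (a*d)/(b*c) with 0.5 added to every cell iff any
    cell is zero; significance is Yates-corrected chi-square when all
    observed and expected values exceed five, else two-sided Fisher.
    """
    a_arr = np.asarray(membership_a, dtype=bool)
    b_arr = np.asarray(membership_b, dtype=bool)
    if a_arr.size == 0 or a_arr.shape != b_arr.shape:
        raise ValueError("memberships must be equal-length and nonempty")
    t = np.array([[(a_arr & b_arr).sum(), (a_arr & ~b_arr).sum()],
                  [(~a_arr & b_arr).sum(), (~a_arr & ~b_arr).sum()]],
                 dtype=float)
    cells = t + 0.5 if (t == 0).any() else t
    odds = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
    expected = t.sum(axis=1, keepdims=True) * t.sum(axis=0, keepdims=True) \
        / t.sum()
    if (t > 5).all() and (expected > 5).all():
        _, p, _, _ = stats.chi2_contingency(t, correction=True)
        test = "yates_chi2"
    else:
        _, p = stats.fisher_exact(t, alternative="two-sided")
        test = "fisher"
    return StatResult(float(odds), float(p), test, int(t.sum()))


# ---------------------------------------------------------------------------
# Knockdown expression shift of element-bound genes

def ks_test(a, b) -> tuple[float, float]:
    """Two-sided two-sample KS (asymptotic p, suited to gene-scale n)."""
    d, p = stats.ks_2samp(a, b, method="asymp")
    return float(d), float(p)


def l1_expression_shift(log2fc: pd.DataFrame, min_tpm: float = 1.0) -> dict:
    """Two-sided KS tests of bound-gene log2FC shifts.

    Expressed genes (TPM >= min_tpm) split into: "bound" (>= 1 bound
    antisense element), "bgd_with_element" (>= 1 element, none bound)
    and "bgd_all" (every expressed gene).  Returns KS results for bound
    vs each background; no multiple-testing correction is applied.
    """
    df = log2fc[log2fc["tpm"] >= min_tpm]
    bound = df[df["n_bound_elements"] >= 1]["log2fc"].to_numpy()
    bgd_el = df[(df["n_elements"] >= 1)
                & (df["n_bound_elements"] == 0)]["log2fc"].to_numpy()
    bgd_all = df["log2fc"].to_numpy()
    for name, grp in (("bound", bound), ("bgd_with_element", bgd_el),
                      ("bgd_all", bgd_all)):
        if len(grp) < 2:
            raise ValueError(f"class {name} has < 2 genes")
    out = {}
    for name, grp in (("bound_vs_bgd_with_element", bgd_el),
                      ("bound_vs_bgd_all", bgd_all)):
        d, p = ks_test(bound, grp)
        out[name] = StatResult(d, p, "ks_2samp", len(bound))
    return out


# ---------------------------------------------------------------------------
# RBP-target enrichment

def rbp_target_enrichment(peak_genes: dict, rbp_genes: set) -> StatResult:
    """Are RBP-encoding mRNAs over-represented among peak-containing genes?

    ``peak_genes`` maps dataset -> set of peak-containing genes.  Per
    dataset, the RBP fraction among its peak-containing genes is divided
    by the pooled background (the RBP share among all peak-containing
    genes across datasets); a one-sample t test compares the per-dataset
    folds against 1.  Datasets with no peak-containing genes are
    excluded with a warning.
    """
    import warnings

    kept = {}
    for d, genes in peak_genes.items():
        if len(genes) == 0:
            warnings.warn(f"{d}: no peak-containing genes, excluded",
                          stacklevel=2)
            continue
        kept[d] = set(genes)
    if len(kept) < 2:
        raise ValueError("need >= 2 datasets with peak-containing genes")
    pooled = set().union(*kept.values())
    background = len(pooled & rbp_genes) / len(pooled)
    if background == 0:
        raise ValueError("no RBP gene appears in any peak set")
    fracs = np.array([len(g & rbp_genes) / len(g) for g in kept.values()])
    folds = fracs / background
    if np.ptp(folds) == 0:  # degenerate: identical folds in every dataset
        t = 0.0 if folds[0] == 1.0 else float(np.sign(folds[0] - 1) * np.inf)
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = stats.ttest_1samp(folds, 1.0)
    return StatResult(float(t), float(p), "one_sample_t", len(folds),
                      {"mean_fold": float(folds.mean()),
                       "median_fraction": float(np.median(fracs)),
                       "background_fraction": background})
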