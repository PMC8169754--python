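"""Backbone-activity inference from differential expression ("iNode" scoring).

A backbone node with enough signed ``r()`` transcripts attached beneath it is
*inferable* (an iNode): its activity in a disease-vs-control contrast is
summarized by the direction-aware Strength statistic

    S(v) = (1 / |G_v|) * sum_{g in G_v} s_g * log2FC_g

where ``G_v`` is the set of the node's attached transcripts that were
measured in the contrast and ``s_g`` is the sign of the backbone->transcript
edge.  S is threshold-free (every measured transcript contributes) and
direction-aware (a repressed target with a negative fold change supports
*activation* of its regulator).

Significance comes from a competitive permutation null: the node's
|G_v| fold changes are redrawn without replacement from the full measured
universe while the edge signs stay fixed.  For small universes the null is
enumerated exactly; otherwise a seeded Monte-Carlo estimate with the
add-one correction ``p = (1 + #{|S*| >= |S|}) / (1 + n_perm)`` is used.
Benjamini-Hochberg adjustment is applied across all iNodes of one contrast.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import NetworkModel

__all__ = [
    "ExpressionContrast",
    "GeneAssignment",
    "INodeIndex",
    "ScoringParams",
    "ScoreResult",
    "ScoreReport",
    "read_contrast",
    "build_inode_index",
    "strength",
    "permutation_pvalue",
    "adjust_pvalues",
    "score_model",
    "scores_to_tsv",
    "scores_from_tsv",
]

#: Comparison tolerance for |S*| >= |S_obs| so that draws that are
#: mathematically tied with the observed statistic (e.g. the identity draw)
#: count as at least as extreme regardless of summation order.
TIE_TOL = 1e-12


@dataclass
class ExpressionContrast:
    """Per-gene log2 fold changes for one disease-vs-control comparison."""

    name: str
    values: dict[str, float]
    pvalues: dict[str, float] | None = None

    def __post_init__(self):
        bad = [g for g, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite fold changes for {bad[:5]}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.values)

    def universe(self) -> np.ndarray:
        """Fold changes of all measured genes, in sorted-gene order (cached)."""
        cached = getattr(self, "_universe", None)
        if cached is None or len(cached) != len(self.values):
            cached = np.array([self.values[g] for g in self.genes], dtype=float)
            object.__setattr__(self, "_universe", cached)
        return cached

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GeneAssignment:
    """A signed backbone->transcript attachment used for scoring."""

    node: str
    gene: str
    sign: int

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("assignment sign must be +1 or -1")


@dataclass
class INodeIndex:
    """Map backbone node id -> transcript assignments (>= min_genes each)."""

    assignments: dict[str, list[GeneAssignment]]
    warnings: list[str] = field(default_factory=list)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class ScoringParams:
    """Tunables for iNode scoring.

    min_genes: minimum measured transcripts for a node to be scored (the
        permutation null is too coarse below ~3 genes).
    n_perm: Monte-Carlo permutations when exact enumeration is too large.
    exact_threshold: maximum number of enumerated null draws for exact mode.
    alpha: BH-adjusted significance level.
    """

    min_genes: int = 3
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    exact_threshold: int = 100_000

    def __post_init__(self):
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")


@dataclass
class ScoreResult:
    node: str
    strength: float
    n_genes: int
    p_perm: float
    p_adj: float
    direction: str  # up / down / null
    significant: bool


@dataclass
class ScoreReport:
    """Scored iNodes plus the nodes that could not be scored."""

    contrast: str
    results: list[ScoreResult]
    unscored: list[tuple[str, str]]  # (node id, reason)

    def __iter__(self):
        return iter(self.results)

    def by_node(self) -> dict[str, ScoreResult]:
        return {r.node: r for r in self.results}


# ---------------------------------------------------------------------------
# contrast IO

def read_contrast(source, name: str = "contrast") -> ExpressionContrast:
    """Read a TSV with columns ``gene``, ``log2fc`` and optional ``pvalue``.

    Gene symbols are upper-cased; duplicate rows for one gene are aggregated
    by the median log2fc (and median p-value).  A non-numeric fold change
    raises with the offending line number (header = line 1).
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "gene" not in df.columns or "log2fc" not in df.columns:
        raise ValueError("contrast table requires 'gene' and 'log2fc' columns")
    fc = pd.to_numeric(df["log2fc"], errors="coerce")
    bad = df.index[fc.isna() & df["log2fc"].notna()]
    if len(bad):
        raise ValueError(
            f"non-numeric log2fc {df.loc[bad[0], 'log2fc']!r} at line {bad[0] + 2}")
    df = df.assign(log2fc=fc).dropna(subset=["log2fc"])
    df["gene"] = df["gene"].str.strip().str.upper()
    values = df.groupby("gene")["log2fc"].median().to_dict()
    pvalues = None
    if "pvalue" in df.columns:
        pv = pd.to_numeric(df["pvalue"], errors="coerce")
        pvalues = df.assign(pvalue=pv).groupby("gene")["pvalue"].median().dropna().to_dict()
    return ExpressionContrast(name, values, pvalues)


# ---------------------------------------------------------------------------
# iNode index

def build_inode_index(model: NetworkModel, params: ScoringParams | None = None) -> INodeIndex:
    """Collect each backbone node's signed HGNC ``r()`` attachments.

    Transcript attachments with conflicting signs (both a +1 and a -1 edge
    from the same backbone node to the same transcript) are *ambivalent*
    and dropped with a warning.  Only nodes with at least ``min_genes``
    unambiguous assignments are indexed.
    """
    params = params or ScoringParams()
    warnings: list[str] = []
    if not model.transcript_nodes():
        warnings.append("model has no transcript layer; empty iNode index")
        return INodeIndex({}, warnings)
    # signs per (backbone, transcript)
    pair_signs: dict[tuple[str, str], set[int]] = {}
    sources_with_out_edges: set[str] = set()
    for e in model.edges.values():
        sources_with_out_edges.add(e.source)
        src = model.nodes[e.source]
        tgt = model.nodes[e.target]
        if src.layer == "backbone" and tgt.layer == "transcript":
            if tgt.term.is_leaf and tgt.term.namespace == "HGNC":
                pair_signs.setdefault((src.id, tgt.id), set()).add(e.sign)
    per_node: dict[str, list[GeneAssignment]] = {}
    for (src_id, tgt_id), signs in sorted(pair_signs.items()):
        gene = model.nodes[tgt_id].term.name.upper()
        if len(signs) > 1:
            warnings.append(f"ambivalent attachment {src_id} -> {tgt_id} dropped")
            continue
        per_node.setdefault(src_id, []).append(
            GeneAssignment(src_id, gene, next(iter(signs))))
    for node in model.transcript_nodes():
        if node.id in sources_with_out_edges:
            warnings.append(f"transcript node {node.id} has outgoing causal edges")
    kept = {nid: lst for nid, lst in per_node.items() if len(lst) >= params.min_genes}
    return INodeIndex(kept, warnings)


# ---------------------------------------------------------------------------
# the Strength statistic

def strength(assignments: list[GeneAssignment],
             contrast: ExpressionContrast) -> tuple[float, int]:
    """Mean edge-sign-weighted log2 fold change over the measured transcripts.

    Genes absent from the contrast are skipped; returns ``(S, n_used)``.
    ``n_used == 0`` leaves the score undefined (``nan``).
    """
    if not assignments:
        raise ValueError("assignments must be nonempty")
    total = 0.0
    n_used = 0
    for a in assignments:
        fc = contrast.values.get(a.gene)
        if fc is None:
            continue
        total += a.sign * fc
        n_used += 1
    if n_used == 0:
        return float("nan"), 0
    return total / n_used, n_used


def _used_signs(assignments: list[GeneAssignment],
                contrast: ExpressionContrast) -> np.ndarray:
    return np.array([a.sign for a in assignments if a.gene in contrast.values], dtype=float)


def _exact_pvalue(universe: np.ndarray, signs: np.ndarray, s_obs: float) -> float:
    """Exhaustive null: every size-n subset of the universe, averaged over
    the distinct ways of assigning drawn values to +/- sign slots."""
    n = len(signs)
    k = int((signs > 0).sum())
    mixed = 0 < k < n
    splits = list(itertools.combinations(range(n), k)) if mixed else [None]
    thr = abs(s_obs) - TIE_TOL
    hits = 0
    total = 0
    for vals in itertools.combinations(universe.tolist(), n):
        sv = sum(vals)
        for plus in splits:
            if plus is None:
                s = sv / n if k == n else -sv / n
            else:
                sp = sum(vals[i] for i in plus)
                s = (2.0 * sp - sv) / n
            total += 1
            if abs(s) >= thr:
                hits += 1
    return hits / total


def _sample_indices(rng: np.random.Generator, universe_size: int, n: int,
                    m: int) -> np.ndarray:
    """m rows of n indices drawn without replacement from range(universe_size);
    row order is a uniformly random arrangement (it matters under mixed signs)."""
    if universe_size <= max(64, 2 * n):
        keys = rng.random((m, universe_size))
        return np.argsort(keys, axis=1)[:, :n]
    idx = rng.integers(0, universe_size, size=(m, n))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, universe_size, size=(int(bad.sum()), n))


def _enum_count(universe_size: int, signs: np.ndarray) -> float:
    n = len(signs)
    k = int((signs > 0).sum())
    count = math.comb(universe_size, n)
    if 0 < k < n:
        count *= math.comb(n, k)
    return count


def permutation_pvalue(assignments: list[GeneAssignment],
                       contrast: ExpressionContrast,
                       params: ScoringParams | None = None,
                       rng: np.random.Generator | None = None) -> float:
    """Two-sided permutation p-value for the node's Strength.

    Null model: redraw the node's ``n_used`` fold changes uniformly without
    replacement from the measured universe, keeping the assignment signs.
    Exact enumeration is used whenever the number of distinguishable null
    draws is at most ``params.exact_threshold``; otherwise a seeded
    Monte-Carlo estimate with the add-one correction.
    """
    params = params or ScoringParams()
    s_obs, n_used = strength(assignments, contrast)
    if n_used == 0:
        raise ValueError("no assigned gene is measured in the contrast")
    universe = contrast.universe()
    if len(universe) < n_used:
        raise ValueError(f"universe size {len(universe)} < set size {n_used}")
    signs = _used_signs(assignments, contrast)
    if _enum_count(len(universe), signs) <= params.exact_threshold:
        return _exact_pvalue(universe, signs, s_obs)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    idx = _sample_indices(rng, len(universe), n_used, params.n_perm)
    s_star = (universe[idx] * signs).mean(axis=1)
    b = int((np.abs(s_star) >= abs(s_obs) - TIE_TOL).sum())
    return (1 + b) / (1 + params.n_perm)


def adjust_pvalues(p_list: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving with input."""
    if len(p_list) == 0:
        return []
    return list(multipletests(p_list, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# full-model scoring

def score_model(model: NetworkModel, contrast: ExpressionContrast,
                params: ScoringParams | None = None) -> ScoreReport:
    """Score every iNode of ``model`` against ``contrast``.

    One ScoreResult per indexed node with at least ``min_genes`` measured
    transcripts; BH adjustment across all scored nodes of this contrast;
    deterministic given ``params.seed`` (per-node generators are spawned
    from it in sorted node-id order).  Unscorable nodes are listed
    separately with a reason instead of raising.
    """
    params = params or ScoringParams()
    index = build_inode_index(model, params)
    node_ids = sorted(index.assignments)
    seeds = np.random.SeedSequence(params.seed).spawn(len(node_ids))
    scored: list[tuple[str, float, int, float]] = []
    unscored: list[tuple[str, str]] = []
    for nid, child in zip(node_ids, seeds):
        assignments = index.assignments[nid]
        s, n_used = strength(assignments, contrast)
        if n_used < params.min_genes:
            unscored.append((nid, f"only {n_used} of {len(assignments)} transcripts measured"))
            continue
        p = permutation_pvalue(assignments, contrast, params,
                               rng=np.random.default_rng(child))
        scored.append((nid, s, n_used, p))
    p_adj = adjust_pvalues([row[3] for row in scored])
    results = []
    for (nid, s, n_used, p), padj in zip(scored, p_adj):
        significant = bool(padj < params.alpha)
        if significant and s > 0:
            direction = "up"
        elif significant and s < 0:
            direction = "down"
        else:
            direction = "null"
        results.append(ScoreResult(nid, s, n_used, p, float(padj), direction, significant))
    return ScoreReport(contrast.name, results, unscored)


# ---------------------------------------------------------------------------
# score table IO

_SCORE_COLUMNS = ["node", "strength", "n_used", "p_perm", "p_adj", "direction"]


def scores_to_tsv(report: ScoreReport) -> str:
    """Deterministic TSV rendering (node id order, fixed float format)."""
    lines = ["\t".join(_SCORE_COLUMNS)]
    for r in report.results:
        lines.append("\t".join([
            r.node,
            f"{r.strength:.10g}",
            str(r.n_genes),
            f"{r.p_perm:.10g}",
            f"{r.p_adj:.10g}",
            r.direction,
        ]))
    return "\n".join(lines) + "\n"


def scores_from_tsv(source, contrast_name: str = "contrast",
                    alpha: float = 0.05) -> ScoreReport:
    """Read a score table written by :func:`scores_to_tsv`."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t")
    results = [
        ScoreResult(row.node, float(row.strength), int(row.n_used),
                    float(row.p_perm), float(row.p_adj), str(row.direction),
                    bool(row.p_adj < alpha))
        for row in df.itertuples()
    ]
    return ScoreReport(contrast_name, results, [])
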