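"""Synthetic two-layer network models with planted backbone activities.

The generator emulates the structure the scoring pipeline consumes: a
backbone of ``act(p(HGNC:...))`` nodes connected by random signed causal
edges, a private set of signed ``r()`` transcript children under each
backbone node, a ``bp()`` process anchor (so dead-end trimming keeps the
graph), and an expression contrast in which each transcript's log2 fold
change is its planted signed effect plus Gaussian noise:

    log2FC_g = s_g * a_v * delta + Normal(0, sigma^2)

where ``a_v`` in {-1, 0, +1} is the planted activity of the transcript's
backbone node and ``s_g`` the attachment sign.  Unattached "null" genes
are pure noise.  Exactly ``floor(frac_active * n_backbone)`` nodes are
active.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bel import BelTerm, EvidenceContext, leaf, wrap
from .model import NetworkModel
from .scoring import ExpressionContrast, ScoreResult

__all__ = ["SyntheticParams", "PlantedTruth", "generate_model",
           "generate_contrast", "recovery_metrics", "contrast_to_tsv"]

_ANCHOR = leaf("bp", "GOBP", "synthetic terminal process")


@dataclass
class SyntheticParams:
    """Generator knobs; defaults are the reference simulation conditions
    (strong, well-separated effects: delta = 2 log2 units against
    sigma = 0.2 noise, ten transcripts per node, half the backbone active).
    """

    n_backbone: int = 100
    edge_prob: float = 0.05
    genes_per_node_mean: float = 10.0
    sign_prob: float = 0.5
    frac_active: float = 0.5
    delta: float = 2.0
    sigma: float = 0.2
    n_null_genes: int = 500
    min_genes: int = 3
    share_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.edge_prob, self.sign_prob, self.frac_active, self.share_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_backbone < 1:
            raise ValueError("n_backbone must be >= 1")


@dataclass
class PlantedTruth:
    """Ground-truth backbone activities keyed by node id."""

    activities: dict[str, int]
    params: SyntheticParams
    gene_map: dict[str, tuple[str, int]] = field(default_factory=dict)  # gene -> (node, sign)

    def active_nodes(self) -> list[str]:
        return sorted(n for n, a in self.activities.items() if a != 0)

    def null_nodes(self) -> list[str]:
        return sorted(n for n, a in self.activities.items() if a == 0)


def _backbone_term(i: int) -> BelTerm:
    return wrap("act", leaf("p", "HGNC", f"SYN{i:04d}"))


def generate_model(params: SyntheticParams) -> tuple[NetworkModel, PlantedTruth]:
    """Build a random two-layer model and its planted truth.

    Backbone node ``i`` is ``act(p(HGNC:SYNnnnn))``; each gets
    ``max(min_genes, Poisson(genes_per_node_mean))`` private ``r()``
    children with attachment sign +1 with probability ``sign_prob``.
    Random backbone->backbone signed edges appear with probability
    ``edge_prob`` per ordered pair, and every backbone node feeds the
    ``bp()`` anchor so the graph survives dead-end trimming.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    n = params.n_backbone
    model = NetworkModel("synthetic", metadata={"generator": "cbnscore.simulate"})
    ev = EvidenceContext(citation="synthetic", evidence_text="generated edge")
    terms = [_backbone_term(i) for i in range(n)]
    for t in terms:
        model.add_term(t)
    model.add_term(_ANCHOR)
    # planted activities: exactly floor(frac_active * n) nonzero
    n_active = math.floor(params.frac_active * n)
    active_idx = rng.choice(n, size=n_active, replace=False)
    act_signs = rng.choice([-1, 1], size=n_active)
    activities = {t.canonical: 0 for t in terms}
    for i, s in zip(active_idx, act_signs):
        activities[terms[i].canonical] = int(s)
    # backbone edges (vectorized Bernoulli draw over the ordered-pair matrix)
    if params.edge_prob > 0:
        mask = rng.random((n, n)) < params.edge_prob
        np.fill_diagonal(mask, False)
        signs = np.where(rng.random((n, n)) < 0.5, 1, -1)
        for i, j in zip(*np.nonzero(mask)):
            model.add_edge(terms[i], terms[j], int(signs[i, j]), evidences=[ev])
    for i in range(n):
        model.add_edge(terms[i], _ANCHOR, +1, evidences=[ev])
    # transcript layer (private children; optional sharing for stress tests)
    gene_map: dict[str, tuple[str, int]] = {}
    for i, t in enumerate(terms):
        k = max(params.min_genes, int(rng.poisson(params.genes_per_node_mean)))
        for g in range(k):
            gene = f"SYN{i:04d}G{g:02d}"
            sign = 1 if rng.random() < params.sign_prob else -1
            model.add_edge(t, leaf("r", "HGNC", gene), sign, evidences=[ev])
            gene_map[gene] = (t.canonical, sign)
            if params.share_prob > 0 and i > 0 and rng.random() < params.share_prob:
                other = terms[int(rng.integers(0, i))]
                model.add_edge(other, leaf("r", "HGNC", gene),
                               1 if rng.random() < params.sign_prob else -1,
                               evidences=[ev])
    return model, PlantedTruth(activities, params, gene_map)


def generate_contrast(model: NetworkModel, truth: PlantedTruth,
                      params: SyntheticParams | None = None,
                      name: str = "synthetic contrast") -> ExpressionContrast:
    """Simulate per-gene log2 fold changes from the planted activities."""
    params = params or truth.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    values: dict[str, float] = {}
    for gene in sorted(truth.gene_map):
        node, sign = truth.gene_map[gene]
        a = truth.activities[node]
        values[gene] = sign * a * params.delta + rng.normal(0.0, params.sigma)
    for i in range(params.n_null_genes):
        values[f"NULL{i:05d}"] = rng.normal(0.0, params.sigma)
    return ExpressionContrast(name, values)


def recovery_metrics(truth: PlantedTruth,
                     results: list[ScoreResult]) -> dict[str, float]:
    """Planted-truth recovery summary.

    sign_recovery: fraction of active nodes whose inferred direction
    matches the planted sign; power: fraction of active nodes called
    significant; type_I: fraction of null nodes called significant.
    Raises if the results contain nodes outside the truth.
    """
    by_node = {r.node: r for r in results}
    extra = sorted(set(by_node) - set(truth.activities))
    if extra:
        raise ValueError(f"scored nodes missing from truth: {extra[:5]}")
    active = truth.active_nodes()
    nulls = truth.null_nodes()
    def _dir(a: int) -> str:
        return "up" if a > 0 else "down"
    n_match = sum(1 for nid in active
                  if nid in by_node and by_node[nid].direction == _dir(truth.activities[nid]))
    n_power = sum(1 for nid in active if nid in by_node and by_node[nid].significant)
    n_fp = sum(1 for nid in nulls if nid in by_node and by_node[nid].significant)
    return {
        "sign_recovery": n_match / len(active) if active else float("nan"),
        "power": n_power / len(active) if active else float("nan"),
        "type_I": n_fp / len(nulls) if nulls else float("nan"),
    }


def contrast_to_tsv(contrast: ExpressionContrast) -> str:
    lines = ["gene\tlog2fc"]
    for gene in contrast.genes:
        lines.append(f"{gene}\t{contrast.values[gene]:.10g}")
    return "\n".join(lines) + "\n"
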