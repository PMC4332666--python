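"""Gene scoring by mutation burden and known-gene enrichment testing.

A gene is elevated by each qualifying (splicing or non-synonymous coding)
variant that survived filtering; truncating and splicing changes weigh more
than missense, silent and intronic changes weigh nothing, and a variant
retained in both members of a kindred pair earns a bonus multiplier.  The
prioritized list is tested for over-representation of known disease genes
with the upper tail of the hypergeometric distribution, optionally alongside
a mutation-rate-weighted baseline probability from a control cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .calls import SampleCallSet, VariantKey
from .cohort import CohortDesign
from .errors import DomainError

logger = logging.getLogger(__name__)

#: Base weights per functional class; truncating/splicing twice missense,
#: silent and intronic changes excluded.
DEFAULT_WEIGHTS: dict[str, float] = {
    "missense": 1.0,
    "splicing": 2.0,
    "nonsense": 2.0,
    "frameshift": 2.0,
    "synonymous": 0.0,
    "intronic": 0.0,
    "other": 0.0,
}

LOF_CLASSES = frozenset({"nonsense", "frameshift", "splicing"})

DEFAULT_PAIR_BONUS = 2.0


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    score: float
    n_qualifying: int
    has_lof: bool
    kindred_supported: bool


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric upper-tail enrichment of known genes in a ranked list.

    k known genes observed among n listed, against K known in the N-gene
    target set; ``fold`` is (k/n)/(K/N).
    """

    k: int
    n: int
    K: int
    N: int
    p_value: float
    fold: float

    @property
    def observed_fraction(self) -> float:
        return self.k / self.n

    @property
    def expected_fraction(self) -> float:
        return self.K / self.N


def score_genes(
    cohort: Sequence[SampleCallSet] | Mapping[str, SampleCallSet],
    design: CohortDesign,
    gene_map: Mapping[VariantKey, str],
    weights: Mapping[str, float] | None = None,
    pair_bonus: float = DEFAULT_PAIR_BONUS,
) -> list[GeneScore]:
    """Rank genes by weighted burden of qualifying variants.

    Each distinct variant key contributes once:
    ``w_base(func_class) * pair_bonus`` if it is retained in both members of
    a declared pair, ``w_base`` otherwise.  Genes with zero score are
    excluded; ties break by (has_lof desc, n_qualifying desc, gene_id asc).
    """
    if isinstance(cohort, Mapping):
        cohort = list(cohort.values())
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    carriers: dict[VariantKey, list[str]] = {}
    func: dict[VariantKey, str] = {}
    for cs in cohort:
        for call in cs:
            carriers.setdefault(call.key, []).append(cs.sample_id)
            func.setdefault(call.key, call.func_class)
    per_gene: dict[str, dict] = {}
    n_unmapped = 0
    for key, samples in carriers.items():
        gene = gene_map.get(key)
        if gene is None:
            n_unmapped += 1
            continue
        base = w.get(func[key], 0.0)
        if base <= 0:
            continue
        pair_shared = any(
            design.kin_of(s) is not None and design.kin_of(s) in samples for s in samples
        )
        contrib = base * (pair_bonus if pair_shared else 1.0)
        g = per_gene.setdefault(gene, {"score": 0.0, "n": 0, "lof": False, "pair": False})
        g["score"] += contrib
        g["n"] += 1
        g["lof"] |= func[key] in LOF_CLASSES
        g["pair"] |= pair_shared
    if n_unmapped:
        logger.info("score_genes: %d variant keys had no gene mapping", n_unmapped)
    scores = [
        GeneScore(gene, v["score"], v["n"], v["lof"], v["pair"])
        for gene, v in per_gene.items()
        if v["score"] > 0
    ]
    scores.sort(key=lambda s: (-s.score, not s.has_lof, -s.n_qualifying, s.gene_id))
    return scores


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Upper-tail probability of drawing >= k known genes in n draws from a
    population of N genes of which K are known, without replacement."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise DomainError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if n == 0:
        raise DomainError("n must be positive")
    p = float(hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K > 0 else float("inf")
    return EnrichmentResult(k=k, n=n, K=K, N=N, p_value=p, fold=fold)


def weighted_baseline(
    gene_mutation_counts: Mapping[str, float], known_genes: Iterable[str]
) -> float:
    """Probability of drawing a known gene when genes are weighted by their
    mutation counts in a control cohort."""
    known = set(known_genes)
    total = float(sum(gene_mutation_counts.values()))
    if total <= 0:
        raise DomainError("total mutation count must be positive")
    return sum(c for g, c in gene_mutation_counts.items() if g in known) / total
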