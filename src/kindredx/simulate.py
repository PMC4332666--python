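"""Synthetic X-exome cohort generator with ground truth.

Emulates the inputs of the kindred filtering pipeline without patient data:
a cohort of sporadic affected males plus affected kindred pairs whose X
chromosomes share recombination-bounded identical-by-descent segments, a
site-frequency panel playing the role of the public reference databases
(with clinical-significance flags and sex-resolved counts), one planted
causal variant per family, and injected error classes — strand-biased,
clustered, batch-systematic, and residual pair discordance.

The model: each kindred pair descends from a maternal line carrying founder
haplotypes.  Recombination breakpoints (a Poisson number per meiosis,
snapped to linkage-block boundaries) partition the chromosome into
intervals; in each interval the two relatives either inherited the same
founder haplotype (identical by descent, probability ``2**-(meioses-1)``)
or different ones.  Inside shared intervals the two call sets agree at
every site by construction; private haplotype variants also travel with
their founder, so discordances arise only outside shared intervals or from
injected errors.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import SampleCallSet, VariantCall, VariantKey
from .cohort import CohortDesign, SampleInfo
from .reference import ReferencePanel

_BASES = np.array(list("ACGT"))

#: effective maternal-line meioses separating the two members of a pair
MEIOSES = {"brothers": 2, "half-brothers": 2, "uncle-nephew": 3, "cousins": 4}

_FUNC_CLASSES = np.array(
    ["intronic", "synonymous", "missense", "other", "splicing", "nonsense", "frameshift"]
)
# ~13% non-synonymous-or-splicing, close to real X-exome call sets
_FUNC_PROBS = np.array([0.62, 0.12, 0.10, 0.13, 0.015, 0.01, 0.005])

_CAUSAL_FUNCS = np.array(["nonsense", "missense", "splicing", "frameshift"])
_CAUSAL_PROBS = np.array([0.35, 0.35, 0.2, 0.1])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Cohort composition mirrors the reference study design (30 sporadic
    affected males; 26 affected pairs: 22 brother, 2 maternal half-brother,
    1 maternal first-cousin, 1 uncle-nephew).  Variant density is scaled to
    ~1,000 variants per sample for test speed; the real cohort carried
    1,774 ± 239.
    """

    n_sporadic: int = 30
    n_brother_pairs: int = 22
    n_half_brother_pairs: int = 2
    n_cousin_pairs: int = 1
    n_uncle_nephew_pairs: int = 1
    chrom: str = "X"
    chrom_length: int = 155_000_000
    par_regions: tuple[tuple[int, int], ...] = ((0, 2_700_000), (154_900_000, 155_000_000))
    n_panel_variants: int = 10_000
    min_site_spacing: int = 25
    freq_alpha: float = 0.2
    freq_beta: float = 2.0
    n_genes: int = 975
    n_known_genes: int = 103
    p_causal_in_known: float = 0.5
    pathogenic_fraction: float = 0.002
    panel_male_chr: int = 525
    panel_female_individuals: int = 567
    evs_male_chr: int = 2_000
    evs_female_chr: int = 2_000
    # fraction of segregating sites each database actually ascertains;
    # chosen so the standalone filter efficiencies mirror real X-exome
    # experience (a dbSNP-style panel removes ~94% of a sample's calls, an
    # EVS-style male subset ~40%, a small internal male call set ~25%)
    dbsnp_ascertainment: float = 0.97
    population_ascertainment: float = 0.30
    evs_ascertainment: float = 0.45
    n_private_per_haplotype: int = 30
    mean_depth: float = 49.0
    crossover_rate_per_meiosis: float = 1.8
    linkage_block_bp: int = 2_000_000
    min_causal_segment_bp: int = 10_000_000
    strand_bias_rate: float = 0.01
    cluster_rate: float = 0.005
    batch_systematic_rate: float = 0.003
    discordance_noise: float = 0.002
    n_popb_samples: int = 0
    batch_size: int = 12
    seed: int = 0

    def n_pairs(self) -> int:
        return (
            self.n_brother_pairs
            + self.n_half_brother_pairs
            + self.n_cousin_pairs
            + self.n_uncle_nephew_pairs
        )

    def relationships(self) -> list[str]:
        return (
            ["brothers"] * self.n_brother_pairs
            + ["half-brothers"] * self.n_half_brother_pairs
            + ["cousins"] * self.n_cousin_pairs
            + ["uncle-nephew"] * self.n_uncle_nephew_pairs
        )


@dataclass
class GroundTruth:
    """What the generator planted, for comparison after filtering."""

    causal: dict[str, dict] = field(default_factory=dict)  # family -> {key, gene, samples}
    shared_segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    errors: dict[str, list] = field(default_factory=dict)  # class -> [(sample, key), ...]
    ancestry: dict[str, str] = field(default_factory=dict)

    def causal_keys(self) -> set[VariantKey]:
        return {tuple(v["key"]) for v in self.causal.values()}

    def error_keys(self, kind: str) -> set[tuple[str, VariantKey]]:
        return {(s, tuple(k)) for s, k in self.errors.get(kind, [])}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


@dataclass
class SimulatedCohort:
    callsets: list[SampleCallSet]
    design: CohortDesign
    truth: GroundTruth
    gene_map: dict[VariantKey, str]
    known_genes: set[str]
    linkage_intervals: list[tuple[int, int]]
    config: SimulationConfig


def gene_spans(config: SimulationConfig) -> tuple[np.ndarray, list[str]]:
    """Equal-width gene spans tiling the chromosome (boundaries, names)."""
    bounds = np.linspace(0, config.chrom_length, config.n_genes + 1).astype(np.int64)
    names = [f"G{i:04d}" for i in range(config.n_genes)]
    return bounds, names


def known_gene_set(config: SimulationConfig) -> set[str]:
    """A deterministic, evenly spread subset of genes marked as known
    disease genes (independent of the simulation seed)."""
    idx = np.unique(np.round(np.linspace(0, config.n_genes - 1, config.n_known_genes)).astype(int))
    assert idx.size == config.n_known_genes
    return {f"G{i:04d}" for i in idx}


def _gene_of(pos: int, bounds: np.ndarray, names: list[str]) -> str:
    i = int(np.searchsorted(bounds, pos - 1, side="right") - 1)
    i = min(max(i, 0), len(names) - 1)
    return names[i]


class _PositionPool:
    """Draws fresh positions keeping a global minimum spacing, outside PARs."""

    def __init__(self, config: SimulationConfig, taken: Sequence[int]) -> None:
        self.cfg = config
        self.taken = sorted(taken)
        lo = config.par_regions[0][1] if config.par_regions else 0
        hi = config.par_regions[-1][0] if config.par_regions else config.chrom_length
        self.lo, self.hi = lo + 1, hi  # 1-based draw range

    def _ok(self, pos: int) -> bool:
        i = bisect_left(self.taken, pos)
        for j in (i - 1, i):
            if 0 <= j < len(self.taken) and abs(self.taken[j] - pos) < self.cfg.min_site_spacing:
                return False
        return True

    def draw(self, rng: np.random.Generator, lo: int | None = None, hi: int | None = None) -> int:
        lo = self.lo if lo is None else max(lo, self.lo)
        hi = self.hi if hi is None else min(hi, self.hi)
        if hi - lo < 2:
            raise ValueError("position range is empty after masking")
        for _ in range(1000):
            pos = int(rng.integers(lo, hi))
            if self._ok(pos):
                insort(self.taken, pos)
                return pos
        raise RuntimeError("could not place a fresh position; region too crowded")

    def reserve(self, pos: int) -> None:
        insort(self.taken, pos)


def simulate_reference_panel(config: SimulationConfig, seed: int) -> ReferencePanel:
    """Fabricate the reference-panel site table.

    Population-A frequencies drive the cohort; carrier counts for the
    dbSNP-like (525 male + 2x567 female chromosomes) and EVS-like panels are
    binomial draws against those frequencies, so the panels behave like
    finite samples of the same population.  A small fraction of low-MAF
    records is flagged pathogenic.
    """
    rng = np.random.default_rng(seed)
    m = config.n_panel_variants
    # positions with global minimum spacing, outside the pseudoautosomal mask
    lo = config.par_regions[0][1] + 1
    hi = config.par_regions[-1][0]
    n_slots = (hi - lo) // config.min_site_spacing
    slots = np.unique(rng.integers(0, n_slots, size=2 * m))
    while slots.size < m:  # top up on the (unlikely) collision-heavy draw
        slots = np.unique(np.concatenate([slots, rng.integers(0, n_slots, size=m)]))
    slots = rng.choice(slots, size=m, replace=False)
    pos = np.sort(lo + slots * config.min_site_spacing)
    f_a = rng.beta(config.freq_alpha, config.freq_beta, m)
    f_b = rng.beta(config.freq_alpha, config.freq_beta, m)
    ref_idx = rng.integers(0, 4, m)
    alt_idx = (ref_idx + rng.integers(1, 4, m)) % 4
    male_cc = rng.binomial(config.panel_male_chr, f_a)
    female_copies = rng.binomial(2 * config.panel_female_individuals, f_a)
    allele_count = male_cc + female_copies
    total_chr = config.panel_male_chr + 2 * config.panel_female_individuals
    maf = allele_count / total_chr
    evs_male = rng.binomial(config.evs_male_chr, f_a)
    evs_female = rng.binomial(config.evs_female_chr, f_a)
    clin = np.full(m, "none", dtype=object)
    low = np.flatnonzero((maf < 0.01) & (allele_count > 0))
    n_path = int(round(config.pathogenic_fraction * m))
    if n_path and low.size:
        chosen = rng.choice(low, size=min(n_path, low.size), replace=False)
        labels = np.where(rng.random(chosen.size) < 0.5, "pathogenic", "probable-pathogenic")
        clin[chosen] = labels
    bounds, names = gene_spans(config)
    genes = [_gene_of(int(p), bounds, names) for p in pos]
    records = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "maf": maf,
            "allele_count": allele_count,
            "male_carrier_count": male_cc,
            "female_only": (male_cc == 0) & (female_copies > 0),
            "hemizygous_annotated": evs_male >= 1,
            "clin_sig": clin,
            "freq_pop_a": f_a,
            "freq_pop_b": f_b,
            "gene_id": genes,
            "func_class": rng.choice(_FUNC_CLASSES, size=m, p=_FUNC_PROBS),
            "present_dbsnp": (allele_count >= 1)
            & (rng.random(m) < config.dbsnp_ascertainment),
            "present_population": (allele_count >= 1)
            & (rng.random(m) < config.population_ascertainment),
            "present_evs": ((evs_male + evs_female) >= 1)
            & (rng.random(m) < config.evs_ascertainment),
        }
    )
    return ReferencePanel(
        records,
        source="synthetic-master",
        n_male_chr=config.panel_male_chr,
        n_female_individuals=config.panel_female_individuals,
    )


def _sample_intervals(
    rng: np.random.Generator, config: SimulationConfig, meioses: int
) -> list[tuple[int, int, bool]]:
    """(start, end, shared) intervals, half-open 0-based, covering the chromosome.

    Breakpoints are snapped to linkage-block boundaries; each interval is
    IBD-shared with probability 2**-(meioses-1).  Resampled until at least
    one shared interval can host a causal variant.
    """
    block_bounds = np.arange(
        config.linkage_block_bp, config.chrom_length, config.linkage_block_bp
    )
    p_share = 2.0 ** -(meioses - 1)
    for _ in range(500):
        k = rng.poisson(meioses * config.crossover_rate_per_meiosis)
        k = min(k, block_bounds.size)
        cuts = np.sort(rng.choice(block_bounds, size=k, replace=False)) if k else np.array([], int)
        edges = np.concatenate(([0], cuts, [config.chrom_length]))
        shared_flags = rng.random(edges.size - 1) < p_share
        intervals = [
            (int(edges[i]), int(edges[i + 1]), bool(shared_flags[i]))
            for i in range(edges.size - 1)
        ]
        if any(s and (e - b) >= config.min_causal_segment_bp for b, e, s in intervals):
            return intervals
    raise RuntimeError("failed to sample a shareable segment structure")


def _attach_reads(
    rng: np.random.Generator,
    keys: list[tuple[VariantKey, str]],
    mean_depth: float,
    guaranteed: set[VariantKey],
) -> list[VariantCall]:
    calls = []
    for key, func in keys:
        depth = int(rng.poisson(mean_depth)) + 1
        fwd = int(rng.binomial(depth, 0.5))
        if key in guaranteed:
            depth = max(depth, 12)
            fwd = int(np.clip(fwd, 2, depth - 2))
        rev = depth - fwd
        calls.append(
            VariantCall(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                genotype=1.0, depth=depth, alt_fwd=fwd, alt_rev=rev, func_class=func,
            )
        )
    return calls


def simulate_cohort(
    config: SimulationConfig, panel: ReferencePanel, seed: int
) -> SimulatedCohort:
    """Generate the cohort call sets, design table and ground truth."""
    rng = np.random.default_rng(seed)
    rec = panel.records
    site_pos = rec["pos"].to_numpy()
    site_ref = rec["ref"].to_numpy()
    site_alt = rec["alt"].to_numpy()
    site_func = rec["func_class"].to_numpy()
    f_a = rec["freq_pop_a"].to_numpy()
    f_b = rec["freq_pop_b"].to_numpy()
    m = site_pos.size
    chrom = config.chrom
    bounds, gene_names = gene_spans(config)
    known = known_gene_set(config)
    known_list = sorted(known)
    unknown_list = sorted(set(gene_names) - known)

    pool = _PositionPool(config, site_pos.tolist())
    truth = GroundTruth(errors={"strand": [], "cluster": [], "batch_systematic": [], "discordance": []})

    # ---- design ----------------------------------------------------------
    sporadic_ids = [f"SPO{i:02d}" for i in range(1, config.n_sporadic + 1)]
    relationships = config.relationships()
    pair_ids = [(f"FAM{i:02d}A", f"FAM{i:02d}B") for i in range(1, len(relationships) + 1)]
    all_ids = sporadic_ids + [s for p in pair_ids for s in p]
    batches = {
        sid: f"L{i // config.batch_size:02d}" for i, sid in enumerate(all_ids)
    }
    design = CohortDesign(
        samples=[SampleInfo(sid, batch=batches[sid]) for sid in all_ids],
        pairs=[(a, b, rel) for (a, b), rel in zip(pair_ids, relationships)],
        sporadic=sporadic_ids,
    )

    def new_variant(sample_freqs_pos: int | None = None, lo=None, hi=None) -> VariantKey:
        p = pool.draw(rng, lo=lo, hi=hi)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return (chrom, p, str(ref), str(alt))

    def plant_causal(family: str, samples: list[str], lo=None, hi=None) -> tuple[VariantKey, str, str]:
        in_known = rng.random() < config.p_causal_in_known
        key = new_variant(lo=lo, hi=hi)
        gene = _gene_of(key[1], bounds, gene_names)
        if (gene in known) != in_known:
            # redraw the position inside a gene of the wanted class that
            # overlaps the allowed range, falling back to the first draw
            wanted = known_list if in_known else unknown_list
            for _ in range(50):
                gname = wanted[int(rng.integers(0, len(wanted)))]
                gi = gene_names.index(gname)
                glo = max(int(bounds[gi]) + 1, lo or 0)
                ghi = min(int(bounds[gi + 1]), hi or config.chrom_length)
                if ghi - glo > 1000:
                    try:
                        key = new_variant(lo=glo, hi=ghi)
                    except ValueError:  # span swallowed by the PAR mask
                        continue
                    gene = gname
                    break
        func = str(rng.choice(_CAUSAL_FUNCS, p=_CAUSAL_PROBS))
        truth.causal[family] = {"key": list(key), "gene": gene, "samples": samples}
        return key, gene, func

    # per-sample accumulation: list of (key, func)
    sample_keys: dict[str, list[tuple[VariantKey, str]]] = {sid: [] for sid in all_ids}
    guaranteed: set[VariantKey] = set()

    # ---- sporadic samples ------------------------------------------------
    for i, sid in enumerate(sporadic_ids):
        truth.ancestry[sid] = "B" if i < config.n_popb_samples else "A"
        freqs = f_b if truth.ancestry[sid] == "B" else f_a
        carried = np.flatnonzero(rng.random(m) < freqs)
        keys = [
            ((chrom, int(site_pos[j]), str(site_ref[j]), str(site_alt[j])), str(site_func[j]))
            for j in carried
        ]
        for _ in range(config.n_private_per_haplotype):
            keys.append((new_variant(), str(rng.choice(_FUNC_CLASSES, p=_FUNC_PROBS))))
        ckey, _, cfunc = plant_causal(sid, [sid])
        keys.append((ckey, cfunc))
        guaranteed.add(ckey)
        sample_keys[sid] = keys

    # ---- kindred pairs ---------------------------------------------------
    for (sid_a, sid_b), rel in zip(pair_ids, relationships):
        family = sid_a[:-1]
        truth.ancestry[sid_a] = truth.ancestry[sid_b] = "A"
        meioses = MEIOSES[rel]
        intervals = _sample_intervals(rng, config, meioses)
        truth.shared_segments[family] = [(b, e) for b, e, s in intervals if s]
        # three founder haplotypes: shared ancestor plus one per branch
        founders = rng.random((3, m)) < f_a
        founder_private: list[list[tuple[VariantKey, str]]] = [[], [], []]
        for fi in range(3):
            for _ in range(config.n_private_per_haplotype):
                founder_private[fi].append(
                    (new_variant(), str(rng.choice(_FUNC_CLASSES, p=_FUNC_PROBS)))
                )
        # founder index per interval for each relative
        assign: dict[str, list[tuple[int, int, int]]] = {sid_a: [], sid_b: []}
        for b, e, shared in intervals:
            if shared:
                assign[sid_a].append((b, e, 0))
                assign[sid_b].append((b, e, 0))
            else:
                assign[sid_a].append((b, e, 1))
                assign[sid_b].append((b, e, 2))
        for sid in (sid_a, sid_b):
            keys: list[tuple[VariantKey, str]] = []
            hap_at = assign[sid]
            # panel sites: pick the active founder at each site
            edges = np.array([b for b, _, _ in hap_at] + [config.chrom_length])
            hap_idx = np.array([h for _, _, h in hap_at])
            site_hap = hap_idx[np.clip(np.searchsorted(edges, site_pos - 1, side="right") - 1, 0, hap_idx.size - 1)]
            carried = np.flatnonzero(founders[site_hap, np.arange(m)])
            keys.extend(
                ((chrom, int(site_pos[j]), str(site_ref[j]), str(site_alt[j])), str(site_func[j]))
                for j in carried
            )
            # founder-private variants travel with their haplotype
            for fi in range(3):
                for key, func in founder_private[fi]:
                    j = int(np.clip(np.searchsorted(edges, key[1] - 1, side="right") - 1, 0, hap_idx.size - 1))
                    if hap_idx[j] == fi:
                        keys.append((key, func))
            sample_keys[sid] = keys
        # causal variant inside a large shared interval, carried by both
        host = max(
            ((b, e) for b, e, s in intervals if s and e - b >= config.min_causal_segment_bp),
            key=lambda iv: iv[1] - iv[0],
        )
        margin = min((host[1] - host[0]) // 10, 500_000)
        ckey, _, cfunc = plant_causal(family, [sid_a, sid_b], lo=host[0] + margin, hi=host[1] - margin)
        guaranteed.add(ckey)
        sample_keys[sid_a].append((ckey, cfunc))
        sample_keys[sid_b].append((ckey, cfunc))

    # ---- injected errors -------------------------------------------------
    n_base = int(np.mean([len(v) for v in sample_keys.values()]))
    error_calls: dict[str, list[VariantCall]] = {sid: [] for sid in all_ids}

    for sid in all_ids:
        for _ in range(rng.poisson(config.strand_bias_rate * n_base)):
            key = new_variant()
            depth = int(rng.integers(3, 15))
            error_calls[sid].append(
                VariantCall(*key, genotype=1.0, depth=depth, alt_fwd=depth, alt_rev=0,
                            func_class="other")
            )
            truth.errors["strand"].append((sid, list(key)))
        for _ in range(rng.poisson(config.cluster_rate * n_base)):
            anchor = pool.draw(rng)
            # cluster members stay within 10 bp of the anchor so the whole
            # run is removed by the proximity rule without touching any
            # neighbouring true call (global spacing >= 25 bp)
            offsets = [0, int(rng.integers(1, 7))]
            if rng.random() < 0.4:
                offsets.append(int(rng.integers(offsets[1] + 1, 11)))
            for off in offsets:
                p = anchor + off
                if off:
                    pool.reserve(p)
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                key = (chrom, p, str(ref), str(alt))
                depth = int(rng.integers(6, 20))
                fwd = int(np.clip(rng.binomial(depth, 0.5), 1, depth - 1))
                error_calls[sid].append(
                    VariantCall(*key, genotype=1.0, depth=depth, alt_fwd=fwd,
                                alt_rev=depth - fwd, func_class="other")
                )
                truth.errors["cluster"].append((sid, list(key)))

    # batch-systematic: same fresh key in >=2 unrelated samples of one batch
    by_batch: dict[str, list[str]] = {}
    for sid in all_ids:
        by_batch.setdefault(batches[sid], []).append(sid)
    for batch, members in sorted(by_batch.items()):
        has_unrelated = any(
            not design.are_kin(a, b)
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        if not has_unrelated:
            continue
        for _ in range(rng.poisson(config.batch_systematic_rate * n_base)):
            key = new_variant()
            while True:
                n_carry = int(rng.integers(2, min(4, len(members)) + 1))
                chosen = list(rng.choice(members, size=n_carry, replace=False))
                if any(
                    not design.are_kin(a, b)
                    for i, a in enumerate(chosen)
                    for b in chosen[i + 1 :]
                ):
                    break
            for sid in chosen:
                depth = int(rng.poisson(config.mean_depth)) + 4
                fwd = int(np.clip(rng.binomial(depth, 0.5), 1, depth - 1))
                error_calls[sid].append(
                    VariantCall(*key, genotype=1.0, depth=depth, alt_fwd=fwd,
                                alt_rev=depth - fwd, func_class="other")
                )
                truth.errors["batch_systematic"].append((sid, list(key)))

    # residual pair discordance inside shared intervals (strand-biased, so
    # the prefilters eliminate it — the erroneous A|R points of real data)
    for (sid_a, sid_b), rel in zip(pair_ids, relationships):
        family = sid_a[:-1]
        shared_ivs = truth.shared_segments[family]
        if not shared_ivs:
            continue
        for _ in range(rng.poisson(config.discordance_noise * n_base)):
            b, e = shared_ivs[int(rng.integers(0, len(shared_ivs)))]
            try:
                key = new_variant(lo=b + 1, hi=e)
            except ValueError:  # interval swallowed by the PAR mask
                continue
            sid = sid_a if rng.random() < 0.5 else sid_b
            depth = int(rng.integers(3, 15))
            error_calls[sid].append(
                VariantCall(*key, genotype=1.0, depth=depth, alt_fwd=depth, alt_rev=0,
                            func_class="other")
            )
            truth.errors["discordance"].append((sid, list(key)))

    # ---- assemble call sets ---------------------------------------------
    callsets = []
    gene_map: dict[VariantKey, str] = {}
    for sid in all_ids:
        calls = _attach_reads(rng, sample_keys[sid], config.mean_depth, guaranteed)
        calls.extend(error_calls[sid])
        cs = SampleCallSet(sid, calls, batch=batches[sid])
        callsets.append(cs)
        for call in cs:
            gene_map.setdefault(call.key, _gene_of(call.pos, bounds, gene_names))

    linkage = [
        (int(b), int(min(b + config.linkage_block_bp, config.chrom_length)))
        for b in range(0, config.chrom_length, config.linkage_block_bp)
    ]
    return SimulatedCohort(
        callsets=callsets,
        design=design,
        truth=truth,
        gene_map=gene_map,
        known_genes=known,
        linkage_intervals=linkage,
        config=config,
    )


@dataclass
class RescueScenario:
    """A cohort where one pathogenic, rare key recurs in two unrelated
    samples and one kindred pair — the configuration that loses a true
    mutation to the cross-cohort rule unless clinical rescue is applied."""

    cohort: SimulatedCohort
    panel: ReferencePanel
    key: VariantKey
    carriers: list[str]


def make_atrx_scenario(seed: int, config: SimulationConfig | None = None) -> RescueScenario:
    """Build the recurrent-pathogenic-variant fixture.

    One nonsense key with pathogenic annotation and MAF 0.2% is planted in
    two unrelated sporadic samples and both members of one brother pair
    (inside a shared interval), mirroring a known recurrent truncating
    mutation in an X-linked disease gene.
    """
    if config is None:
        config = SimulationConfig(
            n_sporadic=6,
            n_brother_pairs=3,
            n_half_brother_pairs=0,
            n_cousin_pairs=0,
            n_uncle_nephew_pairs=0,
            n_panel_variants=2_000,
            n_private_per_haplotype=10,
        )
    panel = simulate_reference_panel(config, seed)
    cohort = simulate_cohort(config, panel, seed + 1)
    rng = np.random.default_rng(seed + 2)
    family = "FAM01"
    pair = [s for s in cohort.design.sample_ids if s.startswith(family)]
    host = max(cohort.truth.shared_segments[family], key=lambda iv: iv[1] - iv[0])
    pool = _PositionPool(
        config, sorted({c.pos for cs in cohort.callsets for c in cs})
    )
    pos = pool.draw(rng, lo=host[0] + 1000, hi=host[1] - 1000)
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    key: VariantKey = (config.chrom, pos, str(ref), str(alt))
    gene = _gene_of(pos, *gene_spans(config))
    cohort.gene_map.setdefault(key, gene)
    carriers = ["SPO01", "SPO02"] + pair
    new_callsets = []
    for cs in cohort.callsets:
        if cs.sample_id in carriers:
            call = VariantCall(*key, genotype=1.0, depth=40, alt_fwd=20, alt_rev=20,
                               func_class="nonsense")
            cs = SampleCallSet(cs.sample_id, list(cs.calls) + [call], batch=cs.batch)
        new_callsets.append(cs)
    cohort.callsets = new_callsets
    row = pd.DataFrame(
        [{
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "maf": 0.002, "allele_count": 3, "male_carrier_count": 0,
            "female_only": True, "hemizygous_annotated": False,
            "clin_sig": "pathogenic", "freq_pop_a": 0.001, "freq_pop_b": 0.001,
            "gene_id": gene, "func_class": "nonsense",
            "present_dbsnp": True, "present_population": False, "present_evs": False,
        }]
    )
    panel = ReferencePanel(
        pd.concat([panel.records, row], ignore_index=True),
        source=panel.source,
        n_male_chr=panel.n_male_chr,
        n_female_individuals=panel.n_female_individuals,
    )
    return RescueScenario(cohort=cohort, panel=panel, key=key, carriers=carriers)


def write_simulation(cohort: SimulatedCohort, panel: ReferencePanel, out_dir: str | Path) -> None:
    """Emit the cohort as files: per-sample VCFs, design TSV, panel TSV,
    truth JSON, linkage BED, gene map TSV and known-gene list."""
    from .io import write_bed_intervals, write_sample_vcf

    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    for cs in cohort.callsets:
        write_sample_vcf(cs, out / "samples" / f"{cs.sample_id}.vcf",
                         contig_length=cohort.config.chrom_length)
    cohort.design.to_tsv(out / "design.tsv")
    panel.to_tsv(out / "panel.tsv")
    cohort.truth.to_json(out / "truth.json")
    write_bed_intervals(cohort.linkage_intervals, out / "linkage.bed", chrom=cohort.config.chrom)
    pd.DataFrame(
        [(k[0], k[1], k[2], k[3], g) for k, g in sorted(cohort.gene_map.items())],
        columns=["chrom", "pos", "ref", "alt", "gene_id"],
    ).to_csv(out / "gene_map.tsv", sep="\t", index=False)
    (out / "known_genes.txt").write_text("\n".join(sorted(cohort.known_genes)) + "\n")
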