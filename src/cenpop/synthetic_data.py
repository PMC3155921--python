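"""Synthetic alignments with the statistical structure of shotgun
population data from yeast point centromeres.

The generator emulates what the analysis assumes about its input: short,
extremely AT-rich (~95% A+T) loci sampled from a panmictic population, with

* finite-sites mutations placed as a Poisson process on the branches of a
  coalescent genealogy (repeat hits allowed, so homoplasy arises naturally),
  with directed substitution rates taken from a configurable 12-entry matrix;
* optional crossovers, modelled as independent genealogies per block rather
  than a full ancestral recombination graph — enough to create four-gamete-
  detectable discordance between blocks;
* slippage indels, at a base rate per site multiplied inside homopolymer
  runs of 5+ bp in the ancestral sequence;
* missing data, applied last as independent per-base masking to ``N``
  (shotgun coverage of the real centromere data leaves only ~40% of sites
  called, which the default emulates).

Genealogies come from msprime (haploid samples, unit population size, so a
pair of lineages coalesces on average one time unit in the past and the
per-site mutation rate is ``theta / 2`` for an expected pairwise diversity of
``theta``).  Everything downstream of the genealogy — root sequence,
mutation typing, indels, masking — is generated here, with full ground truth
returned, and is byte-reproducible under a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from .alignment_io import Alignment
from .cen_annotate import (
    CentromereAnnotation,
    Interval,
)
from .popgen_stats import homopolymer_runs

_BASES = "ACGT"

#: default directed rates: uniform over the 12 substitution types
UNIFORM_MATRIX = {(i, j): 1.0 for i in _BASES for j in _BASES if i != j}

#: AT-rich CDEII-like composition (p_AT = 0.95)
AT_RICH = {"A": 0.475, "C": 0.025, "G": 0.025, "T": 0.475}


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one simulated locus.

    ``theta`` is the expected per-site pairwise diversity; ``missing_fraction``
    defaults to 0.6 so that ~40% of sites per strain carry called bases, as in
    low-coverage shotgun population data.
    """

    n_strains: int = 35
    length: int = 87
    theta: float = 0.02
    base_composition: dict[str, float] = field(default_factory=lambda: dict(AT_RICH))
    substitution_matrix: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(UNIFORM_MATRIX)
    )
    n_crossovers: int = 0
    indel_rate: float = 0.0
    slippage_multiplier: float = 10.0
    run_min_len: int = 5
    missing_fraction: float = 0.6
    seed: int = 1

    def validate(self) -> None:
        if abs(sum(self.base_composition.values()) - 1.0) > 1e-9:
            raise SimulationConfigError("base composition must sum to 1")
        if any(v < 0 for v in self.base_composition.values()):
            raise SimulationConfigError("negative composition fraction")
        if any(v < 0 for v in self.substitution_matrix.values()):
            raise SimulationConfigError("negative substitution rate")
        if not 0 <= self.missing_fraction < 1:
            raise SimulationConfigError("missing_fraction must be in [0, 1)")
        if self.theta < 0 or self.length < 1 or self.n_strains < 2:
            raise SimulationConfigError("need theta >= 0, length >= 1, n >= 2")


@dataclass
class SimulatedLocus:
    """Alignment plus full ground truth for one simulated locus."""

    alignment: Alignment
    pre_masking: Alignment
    newicks: list[str]
    breakpoints: list[int]
    #: (block, site, from_base, to_base, node_time) in placement order
    mutations: list[tuple[int, int, str, str, float]]
    #: (site, kind, length, carrier strains)
    indels: list[tuple[int, str, int, tuple[str, ...]]]
    config: SimulationConfig

    def ground_truth_json(self) -> str:
        return json.dumps(
            {
                "newicks": self.newicks,
                "breakpoints": self.breakpoints,
                "mutations": [
                    {"block": b, "site": s, "from": f, "to": t, "time": tm}
                    for b, s, f, t, tm in self.mutations
                ],
                "indels": [
                    {"site": s, "kind": k, "length": ln, "carriers": list(c)}
                    for s, k, ln, c in self.indels
                ],
                "config": {
                    k: (v if not isinstance(v, dict) else
                        {"|".join(kk) if isinstance(kk, tuple) else kk: vv
                         for kk, vv in v.items()})
                    for k, v in dataclasses.asdict(self.config).items()
                },
            },
            indent=1,
        )


def _random_sequence(rng: np.random.Generator, length: int, comp: dict[str, float]) -> np.ndarray:
    probs = np.array([comp[b] for b in _BASES])
    return rng.choice(np.frombuffer(_BASES.encode(), dtype="S1"), size=length, p=probs)


def _mutate_base(rng: np.random.Generator, base: str, matrix: dict) -> str:
    targets = [j for j in _BASES if j != base]
    w = np.array([matrix[(base, j)] for j in targets], dtype=float)
    if w.sum() == 0:
        return base
    return rng.choice(targets, p=w / w.sum())


def simulate_coalescent_alignment(cfg: SimulationConfig) -> SimulatedLocus:
    """Simulate one locus under the configured study conditions.

    With ``n_crossovers > 0`` the locus is split at uniformly drawn
    breakpoints into blocks whose genealogies are independent.  Within a
    block, the total mutation count is Poisson with mean
    ``(theta/2) * total branch length * block length`` and each mutation
    lands on a branch (weighted by length) and a uniform site; repeated hits
    on a site yield homoplasy.  Indels and N-masking follow; all randomness
    derives from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # block structure
    if cfg.n_crossovers > 0:
        inner = sorted(
            int(x) for x in rng.choice(
                np.arange(1, cfg.length), size=cfg.n_crossovers, replace=False
            )
        )
    else:
        inner = []
    bounds = [0] + inner + [cfg.length]
    blocks = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    strain_ids = [f"strain{c:03d}" for c in range(cfg.n_strains)]
    seqs = {sid: np.empty(0, dtype="S1") for sid in strain_ids}
    newicks: list[str] = []
    mutations: list[tuple[int, int, str, str, float]] = []

    for bi, (bstart, bend) in enumerate(blocks):
        blen = bend - bstart
        ts = msprime.sim_ancestry(
            samples=cfg.n_strains,
            ploidy=1,
            population_size=1.0,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        tree = ts.first()
        newicks.append(tree.as_newick())
        root_seq = _random_sequence(rng, blen, cfg.base_composition)

        # per-sample sequences start as the root sequence
        block_seqs = {u: root_seq.copy() for u in range(cfg.n_strains)}

        # The matrix holds relative *directed* rates, so a base's total
        # mutation rate is its row sum.  Proposals arrive at the maximum row
        # rate and are thinned by the current base's row total; with a
        # uniform matrix every proposal is accepted and E[pi] = theta.
        row_total = {
            i: sum(cfg.substitution_matrix[(i, j)] for j in _BASES if j != i)
            for i in _BASES
        }
        max_row = max(row_total.values())
        mu = cfg.theta / 2.0
        total_branch = sum(
            tree.branch_length(u) for u in tree.nodes() if u != tree.root
        )
        n_mut = rng.poisson(mu * total_branch * blen) if max_row > 0 else 0
        if n_mut:
            edges = [u for u in tree.nodes() if u != tree.root]
            weights = np.array([tree.branch_length(u) for u in edges])
            weights = weights / weights.sum()
            mut_edges = rng.choice(len(edges), size=n_mut, p=weights)
            mut_sites = rng.integers(0, blen, size=n_mut)
            # ages within each branch, so repeat hits apply in time order
            ages = np.array(
                [
                    ts.nodes_time[edges[e]] + rng.uniform() * tree.branch_length(edges[e])
                    for e in mut_edges
                ]
            )
            order = np.argsort(-ages)  # oldest first
            # propagate: for each mutation (old -> young), flip the site in
            # all samples below that edge, based on their current state
            samples_below = {
                u: np.fromiter(tree.samples(edges[u_i]), dtype=int)
                for u_i, u in enumerate(range(len(edges)))
            }
            for k in order:
                e_i = int(mut_edges[k])
                site = int(mut_sites[k])
                below = samples_below[e_i]
                cur = block_seqs[int(below[0])][site].decode()
                if rng.uniform() * max_row > row_total[cur]:
                    continue  # thinned proposal
                new = _mutate_base(rng, cur, cfg.substitution_matrix)
                for s in below:
                    block_seqs[int(s)][site] = new.encode()
                mutations.append(
                    (bi, bstart + site, cur, new, float(ages[k]))
                )

        for u, sid in enumerate(strain_ids):
            seqs[sid] = np.concatenate([seqs[sid], block_seqs[u]])

    records = [(sid, seqs[sid].tobytes().decode()) for sid in strain_ids]

    # indels (slippage-aware), applied on the assembled alignment
    indel_events: list[tuple[int, str, int, tuple[str, ...]]] = []
    if cfg.indel_rate > 0:
        records, indel_events = _apply_indels(rng, records, cfg)

    pre_mask = Alignment(f"sim_seed{cfg.seed}", tuple(records))
    masked = degrade_alignment(
        pre_mask, cfg.missing_fraction, seed=int(rng.integers(0, 2**31 - 1))
    )
    return SimulatedLocus(
        alignment=masked,
        pre_masking=pre_mask,
        newicks=newicks,
        breakpoints=inner,
        mutations=mutations,
        indels=indel_events,
        config=cfg,
    )


def _apply_indels(
    rng: np.random.Generator,
    records: list[tuple[str, str]],
    cfg: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[tuple[int, str, int, tuple[str, ...]]]]:
    """Drop +/-1 bp slippage events on random subsets of strains.

    The per-site event rate is ``indel_rate``, multiplied by
    ``slippage_multiplier`` where the consensus (first) sequence sits inside a
    homopolymer run of ``run_min_len``+.  Deletions replace the carrier's base
    with '-'; insertions add a column in which only carriers hold a base.
    """
    L = len(records[0][1])
    context = records[0][1]
    prof = homopolymer_runs(context, min_len=cfg.run_min_len)
    rates = np.full(L, cfg.indel_rate)
    for _, s, e in prof.runs:
        rates[s:e] *= cfg.slippage_multiplier
    n_events = rng.poisson(rates.sum())
    sites = rng.choice(L, size=n_events, p=rates / rates.sum()) if n_events else []
    events: list[tuple[int, str, int, tuple[str, ...]]] = []
    cols = {sid: list(seq) for sid, seq in records}
    inserts: dict[int, list[tuple[str, tuple[str, ...]]]] = {}
    for site in sorted(int(s) for s in sites):
        kind = "deletion" if rng.uniform() < 0.5 else "insertion"
        n_carriers = max(1, int(rng.integers(1, max(2, len(records) // 3))))
        carriers = tuple(
            sorted(rng.choice([sid for sid, _ in records], size=n_carriers, replace=False))
        )
        if kind == "deletion":
            for sid in carriers:
                cols[sid][site] = "-"
        else:
            base = context[site] if context[site] in _BASES else "A"
            inserts.setdefault(site, []).append((base, carriers))
        events.append((site, kind, 1, carriers))
    if inserts:
        for site in sorted(inserts, reverse=True):
            for base, carriers in inserts[site]:
                for sid in cols:
                    cols[sid].insert(site, base if sid in carriers else "-")
    return [(sid, "".join(cols[sid])) for sid, _ in records], events


def degrade_alignment(
    aln: Alignment, missing_fraction: float, seed: int = 0
) -> Alignment:
    """Mask each valid base independently to ``N`` with the given probability
    (gaps are left untouched); deterministic under ``seed``."""
    if not 0 <= missing_fraction < 1:
        raise SimulationConfigError("missing_fraction must be in [0, 1)")
    if missing_fraction == 0:
        return aln
    rng = np.random.default_rng(seed)
    out = []
    for sid, seq in aln.records:
        mask = rng.uniform(size=len(seq)) < missing_fraction
        chars = [
            "N" if (m and c in _BASES) else c for c, m in zip(seq, mask)
        ]
        out.append((sid, "".join(chars)))
    return Alignment(aln.locus_id, tuple(out))


def plant_centromere_sequence(
    cdei_instance: str = "GTCACGTG",
    cdeii_length: int = 87,
    cdeiii_instance: str = "TGTATATTGATTTATAAATTCCCGA",
    flank_length: int = 100,
    base_composition: dict[str, float] | None = None,
    reverse_complement: bool = False,
    seed: int = 0,
) -> tuple[str, CentromereAnnotation]:
    """Construct a raw sequence with a planted point centromere.

    Returns the sequence and the ground-truth annotation (forward
    coordinates, strand reflecting ``reverse_complement``).  The default
    element instances match the shipped CDEI/CDEIII consensus patterns; the
    CDEII filler is AT-rich.
    """
    from Bio.Seq import Seq

    comp = base_composition or dict(AT_RICH)
    rng = np.random.default_rng(seed)

    def rand(n: int, c: dict[str, float]) -> str:
        return _random_sequence(rng, n, c).tobytes().decode()

    # GC-leaning flanks so the AT-rich filler cannot spawn spurious motifs
    flank_comp = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    left = rand(flank_length, flank_comp)
    cdeii = rand(cdeii_length, comp)
    right = rand(flank_length, flank_comp)
    seq = left + cdei_instance + cdeii + cdeiii_instance + right
    i1 = Interval(flank_length, flank_length + len(cdei_instance))
    i2 = Interval(i1.end, i1.end + cdeii_length)
    i3 = Interval(i2.end, i2.end + len(cdeiii_instance))
    strand = "+"
    if reverse_complement:
        L = len(seq)
        seq = str(Seq(seq).reverse_complement())
        i1, i3 = (
            Interval(L - i1.end, L - i1.start),
            Interval(L - i3.end, L - i3.start),
        )
        i2 = Interval(i3.end, i1.start)
        strand = "-"
    return seq, CentromereAnnotation(
        source_id="planted", strand=strand, cdei=i1, cdeii=i2, cdeiii=i3
    )


def write_locus(locus: SimulatedLocus, fasta_path: str | Path, truth_path: str | Path) -> None:
    from .alignment_io import write_alignment

    write_alignment(locus.alignment, fasta_path)
    Path(truth_path).write_text(locus.ground_truth_json())
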