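"""End-to-end orchestration: annotate, per-region statistics, recombination
testing, and the mutation spectrum, over a directory of per-locus alignments.

Regions (centromere core vs flanks) come from configuration rather than from
the annotation stage, so an annotation failure on one locus does not silence
its downstream statistics; the core is analysed separately from the flanks
because the homoplasy null assumes a uniform mutation rate, which does not
hold across the core/flank boundary.  All randomized stages draw independent
named seeds derived from a single master seed, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment_io import Alignment, read_alignment, reduce_to_haplotypes
from .mutation_spectrum import (
    classify_indels,
    polarize_unique_changes,
    relative_rates_with_ci,
    spectrum_counts,
)
from .popgen_stats import bootstrap_ci, polymorphism_summary
from .recombination import analyse_region, retest_after_removal

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    #: locus_id -> {region name -> [start, end]} (1-based inclusive in config)
    regions: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    population_map: str | None = None
    master_seed: int = 1
    bootstrap_reps: int = 10_000
    homoplasy_reps: int = 1000
    spectrum_boot_reps: int = 1000
    max_cover_vertices: int = 32
    homoplasy_condition: str = "distinct"
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        """A named per-stage seed derived reproducibly from the master seed."""
        ss = np.random.SeedSequence(
            [self.master_seed, abs(hash_stage(stage)) % 2**31]
        )
        return int(ss.generate_state(1)[0] % 2**31)


def hash_stage(stage: str) -> int:
    # stable across processes (unlike builtin hash of str)
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 2**31
    return h


def _region_slice(region: list[int]) -> tuple[int, int]:
    """Config regions are 1-based inclusive; internally 0-based half-open."""
    start, end = region
    return start - 1, end


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage over all loci in ``cfg.input_dir`` and write per-stage
    TSV/JSON reports plus a run manifest under ``cfg.output_dir``.

    Per-locus failures are logged and isolated unless ``cfg.strict``.
    Returns the report bundle as a dict.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastas = sorted(Path(cfg.input_dir).glob("*.fa")) + sorted(
        Path(cfg.input_dir).glob("*.fasta")
    )
    if not fastas:
        raise FileNotFoundError(f"no FASTA alignments in {cfg.input_dir}")

    loci: dict[str, Alignment] = {}
    for p in fastas:
        try:
            loci[p.stem] = read_alignment(p)
        except Exception:
            if cfg.strict:
                raise
            logger.exception("skipping unreadable locus %s", p)

    stats_rows = []
    recomb_rows = []
    spectra = []
    spectrum_loci = []
    errors: dict[str, str] = {}

    for locus_id, aln in loci.items():
        regions = {
            name: _region_slice(iv)
            for name, iv in cfg.regions.get(locus_id, {}).items()
        } or {"whole": (0, aln.length)}
        try:
            removed_all: set[int] = set()
            for name, reg in regions.items():
                summ = polymorphism_summary(aln, reg)
                stats_rows.append(
                    {
                        "locus": locus_id,
                        "region": name,
                        "start": reg[0] + 1,
                        "end": reg[1],
                        "n_sites": summ.n_sites_analysed,
                        "S": summ.S,
                        "pi": summ.pi,
                        "theta_w": summ.theta_w,
                    }
                )
                res = analyse_region(
                    aln,
                    reg,
                    n_reps=cfg.homoplasy_reps,
                    seed=cfg.stage_seed(f"homoplasy/{locus_id}/{name}"),
                    max_vertices=cfg.max_cover_vertices,
                    condition=cfg.homoplasy_condition,
                )
                removed_all.update(res.min_homoplasy_set)
                recomb_rows.append(
                    {
                        "locus": locus_id,
                        "region": name,
                        "S": summ.S,
                        "n_incompatible_pairs": len(res.incompatible_pairs),
                        "rmin": res.rmin,
                        "k_obs": res.k_obs,
                        "p_value": res.p_value,
                        "removed_sites_1based": ",".join(
                            str(c + 1) for c in res.min_homoplasy_set
                        ),
                    }
                )
            n_after = len(retest_after_removal(aln, removed_all))
            recomb_rows.append(
                {
                    "locus": locus_id,
                    "region": "full_after_removal",
                    "S": "",
                    "n_incompatible_pairs": n_after,
                    "rmin": "",
                    "k_obs": "",
                    "p_value": "",
                    "removed_sites_1based": ",".join(
                        str(c + 1) for c in sorted(removed_all)
                    ),
                }
            )

            reduced = reduce_to_haplotypes(aln).reduced
            changes = polarize_unique_changes(reduced)
            spectra.append(spectrum_counts(reduced, changes))
            spectrum_loci.append(
                {
                    "locus": locus_id,
                    "n_haplotypes": reduced.n_strains,
                    "n_changes": len(changes),
                    "indels": dataclasses.asdict(classify_indels(reduced))
                    | {"events": None},
                }
            )
        except Exception as exc:
            if cfg.strict:
                raise
            logger.exception("locus %s failed", locus_id)
            errors[locus_id] = repr(exc)

    # pooled outputs
    pi_values = [
        r["pi"] for r in stats_rows if r["region"] in ("whole", "CDEII")
    ]
    bundle: dict = {
        "stats": stats_rows,
        "recombination": recomb_rows,
        "spectrum_loci": spectrum_loci,
        "errors": errors,
    }
    if len(pi_values) >= 2:
        est = bootstrap_ci(
            pi_values,
            "mean",
            n_reps=cfg.bootstrap_reps,
            seed=cfg.stage_seed("bootstrap/pi"),
        )
        bundle["pi_mean"] = dataclasses.asdict(est)
    if any(c.total for c in spectra):
        rates = relative_rates_with_ci(
            spectra,
            n_reps=cfg.spectrum_boot_reps,
            seed=cfg.stage_seed("spectrum/bootstrap"),
        )
        bundle["relative_rates"] = {
            "r": rates.r,
            "ci_low": rates.ci_low,
            "ci_high": rates.ci_high,
        }

    _write_tsv(outdir / "stats.tsv", stats_rows)
    _write_tsv(outdir / "recombination.tsv", recomb_rows)
    (outdir / "spectrum.json").write_text(
        json.dumps(
            {k: bundle[k] for k in ("spectrum_loci", "relative_rates") if k in bundle},
            indent=1,
        )
    )
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "n_loci": len(loci),
        "n_failed": len(errors),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if errors and not cfg.strict:
        logger.warning("%d loci failed: %s", len(errors), sorted(errors))
    return bundle


def _write_tsv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0].keys())
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r.get(c, "")) for c in cols))
    path.write_text("\n".join(lines) + "\n")
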