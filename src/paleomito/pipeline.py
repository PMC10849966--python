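"""End-to-end orchestration: filter -> dedup -> damage -> contamination ->
mode selection -> taxonomy -> consensus (-> compare -> date), driven by a
YAML config, with a machine-readable JSON report.

The report isolates its timestamp in a single field so that reruns under a
fixed seed are byte-comparable on the remainder.
"""

from __future__ import annotations

import contextlib
import datetime
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, compare, consensus, damage, simulate, taxonomy, tipdating

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(name, exc) from exc


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    ``sam``, ``reference`` and ``outdir`` are required; ``diagnostic_table``,
    ``compare_fasta`` and ``calibration_fasta`` + ``tip_dates`` (TSV with
    columns id, years_bp, is_calibration, is_outgroup) switch on the
    optional stages.  Unknown keys in the YAML are rejected.
    """

    sam: str
    reference: str
    outdir: str
    diagnostic_table: str | None = None
    compare_fasta: str | None = None
    calibration_fasta: str | None = None
    tip_dates: str | None = None
    query_id: str = "query"
    min_length: int = 35
    min_mapq: int = 25
    damage_window: int = 15
    terminal_window: int = 3
    mask_window: int = 7
    min_coverage: int = 5
    min_support: float = 0.80
    contamination_threshold: float = 0.05
    error_rate: float = 0.001
    min_overlap: int = 1000
    n_boot: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.min_support <= 1.0:
            raise ValueError("min_support must be in (0.5, 1]")
        for key in ("min_length", "min_mapq", "mask_window", "min_coverage",
                    "damage_window", "terminal_window", "min_overlap", "n_boot"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be >= 0")
        if not 0 <= self.contamination_threshold <= 1:
            raise ValueError("contamination_threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        missing = {"sam", "reference", "outdir"} - set(raw)
        if missing:
            raise ValueError(f"missing required config key(s): {sorted(missing)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for key in ("sam", "reference", "diagnostic_table", "compare_fasta",
                    "calibration_fasta", "tip_dates"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {key} does not exist: {value}")


def load_reference(path) -> simulate.ReferenceGenome:
    seqs = simulate.read_fasta(path)
    if len(seqs) != 1:
        raise ValueError(
            f"reference FASTA must contain exactly one record, has {len(seqs)}"
        )
    name, seq = next(iter(seqs.items()))
    return simulate.ReferenceGenome(name=name, sequence=seq, circular=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; writes artefacts plus report.json to
    ``config.outdir`` and returns the report dict."""
    with _stage("config"):
        config.validate_paths()
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref = load_reference(config.reference)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": asdict(config),
        "stages": {},
    }

    with _stage("read_filter_dedup"):
        frags, stats = alignment.read_sam(config.sam, ref, with_stats=True)
        filtered = alignment.filter_fragments(frags, config.min_length, config.min_mapq)
        fragments = alignment.deduplicate(filtered)
        report["stages"]["read_filter_dedup"] = {
            "n_records_mapped": stats.n_mapped,
            "n_unmapped_skipped": stats.n_unmapped_skipped,
            "n_after_filter": len(filtered),
            "n_after_dedup": len(fragments),
        }

    with _stage("damage_profile"):
        prof = damage.damage_profile(fragments, ref, window=config.damage_window)
        prof.to_dataframe().to_csv(outdir / "damage_profile.tsv", sep="\t", index=False)
        report["stages"]["damage_profile"] = {
            "ct5_terminal": None if np.isnan(prof.ct5[0]) else float(prof.ct5[0]),
            "ct3_terminal": None if np.isnan(prof.ct3[0]) else float(prof.ct3[0]),
            "artifact": "damage_profile.tsv",
        }

    with _stage("contamination"):
        est = damage.estimate_contamination(
            fragments, ref, config.error_rate,
            terminal_window=config.terminal_window,
            n_boot=config.n_boot, seed=config.seed,
        )
        contamination_payload = {
            "point": est.point, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "p_terminal": est.p_terminal, "p_conditional": est.p_conditional,
            "n_conditioning": est.n_conditioning, "n_fragments": est.n_fragments,
        }
        with open(outdir / "contamination.json", "w") as fh:
            json.dump(contamination_payload, fh, indent=2)
        report["stages"]["contamination"] = contamination_payload

    mode = consensus.select_mode(est, config.contamination_threshold)
    report["mode_selected"] = mode

    if config.diagnostic_table:
        with _stage("taxonomy"):
            table = taxonomy.read_diagnostic_table(config.diagnostic_table)
            assignment = taxonomy.assign_lineage(
                fragments, table, damage_aware=True, mask_window=config.mask_window
            )
            with open(outdir / "lineage_assignment.json", "w") as fh:
                json.dump(assignment.to_dict(), fh, indent=2)
            report["stages"]["taxonomy"] = assignment.to_dict()

    with _stage("consensus"):
        params = consensus.ConsensusParams(
            min_coverage=config.min_coverage,
            min_support=config.min_support,
            mask_window=config.mask_window,
            mode=mode,
            contamination_threshold=config.contamination_threshold,
        )
        flags = damage.deaminated_flags(fragments, ref, config.terminal_window)
        genome = consensus.call_consensus(fragments, ref, params, deaminated_flags=flags)
        consensus.write_consensus(
            genome, outdir / "consensus.fasta", outdir / "consensus_sites.tsv",
            name=config.query_id,
        )
        report["stages"]["consensus"] = genome.summary()

    if config.compare_fasta:
        with _stage("compare"):
            others = simulate.read_fasta(config.compare_fasta)
            matrix = compare.difference_matrix(
                {config.query_id: genome.sequence, **others}
            )
            matrix.write(outdir / "n_diff.tsv", outdir / "n_compared.tsv")
            payload = {
                "groups": compare.zero_difference_groups(matrix, config.min_overlap),
                "low_overlap_zero_pairs": compare.low_overlap_zero_pairs(
                    matrix, config.min_overlap
                ),
            }
            with open(outdir / "matriline_groups.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            report["stages"]["compare"] = payload

    if config.calibration_fasta and config.tip_dates:
        with _stage("tip_dating"):
            aln = simulate.read_fasta(config.calibration_fasta)
            aln[config.query_id] = genome.sequence
            dates_df = pd.read_csv(config.tip_dates, sep="\t")
            tip_dates = {
                str(row.id): float(row.years_bp)
                for row in dates_df.itertuples(index=False)
                if bool(getattr(row, "is_calibration", True))
            }
            outgroups = [
                str(row.id) for row in dates_df.itertuples(index=False)
                if bool(getattr(row, "is_outgroup", False))
            ]
            est_date = tipdating.estimate_tip_date(
                aln, tip_dates, config.query_id, outgroups,
                n_boot=config.n_boot, seed=config.seed,
            )
            with open(outdir / "tip_date.json", "w") as fh:
                json.dump(est_date.to_dict(), fh, indent=2)
            report["stages"]["tip_dating"] = est_date.to_dict()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
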