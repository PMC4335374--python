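"""End-to-end sample analysis: align -> pileup -> call -> phase -> isoforms.

One call produces every table the assay reports for a sample: the variant
table, the clone-composition table with compound/independent pair calls,
the isoform table, and a JSON summary (read counts, mapped/full-length
percentages, per-variant frequencies, clone composition, isoforms). All
outputs are plain standard formats (FASTQ/SAM/TSV/VCF/JSON/FASTA) so any
stage can be inspected or replaced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, align, clonal, isoforms as isoforms_mod, variants as variants_mod
from .refmodel import Amplicon
from .reads import CcsRead


@dataclass
class RunConfig:
    """Configuration of one pipeline run; the seed only matters for the
    simulate subcommand but is recorded in every summary for provenance."""

    caller: variants_mod.CallerConfig = field(default_factory=variants_mod.CallerConfig)
    gap_params: align.GapParams = field(default_factory=align.GapParams)
    min_identity: float = 0.75
    end_tolerance: int = 5
    window_half_width: int = 10
    isoform_mode: str = "event"
    isoform_min_support: int = 2
    isoform_min_event_length: int = 3
    seed: int | None = None


@dataclass
class SampleReport:
    alignments: list
    n_reads: int
    n_unmapped: int
    pileup: align.Pileup
    error_floor: float
    variant_calls: list
    clone_table: clonal.CloneTable | None
    isoform_table: isoforms_mod.IsoformTable | None

    def summary(self) -> dict:
        n_mapped = len(self.alignments)
        n_full = sum(a.full_length for a in self.alignments)
        doc = {
            "version": __version__,
            "reads": self.n_reads,
            "mapped": n_mapped,
            "mapped_pct": round(100.0 * n_mapped / self.n_reads, 3) if self.n_reads else 0.0,
            "full_length": n_full,
            "full_length_pct": round(100.0 * n_full / n_mapped, 3) if n_mapped else 0.0,
            "error_floor": round(self.error_floor, 6),
            "variants": [
                {
                    "label": c.label,
                    "position": c.position + 1,
                    "ref": c.ref,
                    "alt": c.alt,
                    "frequency_pct": round(100.0 * c.frequency, 4),
                }
                for c in self.variant_calls
            ],
        }
        if self.clone_table is not None:
            doc["clones"] = [
                {"signature": sorted(sig) or ["none"], "frequency_pct": round(f, 4)}
                for sig, _, f in self.clone_table.rows
            ]
            doc["excluded_reads"] = self.clone_table.excluded
            doc["pairs"] = {
                f"{a}+{b}": pc.classification for (a, b), pc in self.clone_table.pairs.items()
            }
        if self.isoform_table is not None:
            doc["isoforms"] = [
                {
                    "label": r.label,
                    "support": r.support,
                    "frequency_pct": round(r.frequency, 4),
                }
                for r in self.isoform_table.records
            ]
        return doc


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def run_pipeline(
    reads: list[CcsRead], amplicon: Amplicon, config: RunConfig | None = None
) -> SampleReport:
    """Analyze one sample in memory; see the CLI ``run`` subcommand for the
    file-based equivalent."""
    config = config or RunConfig()
    try:
        alns, unmapped = align.align_reads(
            reads,
            amplicon,
            params=config.gap_params,
            min_identity=config.min_identity,
            end_tolerance=config.end_tolerance,
        )
        if not alns:
            raise ValueError("no reads aligned to the amplicon")
        pile = align.pileup(alns, amplicon)
    except Exception as err:
        raise StageError(f"align: {err}") from err

    try:
        floor = (
            config.caller.error_floor
            if config.caller.error_floor is not None
            else variants_mod.estimate_error_floor(pile)
        )
        calls = variants_mod.annotate_all(
            variants_mod.call_variants(
                pile,
                variants_mod.CallerConfig(
                    min_frequency=config.caller.min_frequency,
                    min_alt_count=config.caller.min_alt_count,
                    error_floor=floor,
                    alpha=config.caller.alpha,
                ),
            ),
            amplicon,
        )
    except Exception as err:
        raise StageError(f"call: {err}") from err

    clone_table = None
    if calls:
        try:
            sigs = clonal.signatures_for(alns, calls, config.window_half_width)
            clone_table = clonal.composition(sigs)
        except Exception as err:
            raise StageError(f"phase: {err}") from err

    isoform_table = None
    if any(a.full_length for a in alns):
        try:
            isoform_table = isoforms_mod.detect_isoforms(
                alns,
                amplicon,
                mode=config.isoform_mode,
                min_support=config.isoform_min_support,
                min_event_length=config.isoform_min_event_length,
            )
        except Exception as err:
            raise StageError(f"isoforms: {err}") from err

    return SampleReport(
        alignments=alns,
        n_reads=len(reads),
        n_unmapped=unmapped,
        pileup=pile,
        error_floor=floor,
        variant_calls=calls,
        clone_table=clone_table,
        isoform_table=isoform_table,
    )


def write_report(report: SampleReport, amplicon: Amplicon, outdir, config: RunConfig | None = None) -> None:
    """Write all tables plus the JSON summary into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    align.write_sam(report.alignments, amplicon, outdir / "alignments.sam")
    variants_mod.write_variants_tsv(report.variant_calls, outdir / "variants.tsv")
    variants_mod.write_vcf(report.variant_calls, amplicon, outdir / "variants.vcf")
    if report.clone_table is not None:
        report.clone_table.to_frame().to_csv(outdir / "clones.tsv", sep="\t", index=False)
        (outdir / "clones.json").write_text(report.clone_table.to_json())
    if report.isoform_table is not None:
        report.isoform_table.to_frame().to_csv(outdir / "isoforms.tsv", sep="\t", index=False)
        (outdir / "isoforms.json").write_text(report.isoform_table.to_json())
        isoforms_mod.write_isoform_fasta(report.isoform_table, amplicon, outdir / "isoforms.fasta")
    summary = report.summary()
    if config is not None and config.seed is not None:
        summary["seed"] = config.seed
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
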