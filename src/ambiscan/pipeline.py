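"""End-to-end orchestration: scan -> blocks -> haplotypes -> codons ->
structure -> cluster, driven by a YAML-serialisable configuration.

Every number in the summary JSON is reproducible by calling the
corresponding module operation alone with the parameters logged next to it;
the pipeline only sequences the stages and serialises their outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .codons import CodingFrame, summarize_coding
from .fingerprint import distance_matrix, distinct_patterns, filter_bands, upgma
from .haplotypes import enumerate_haplotypes, otu_split
from .io import (
    read_band_matrix,
    read_fasta,
    read_vienna,
    write_census_json,
    write_fasta,
    write_sites_tsv,
)
from .scan import detect_blocks, scan_alignment
from .structure import site_context

log = logging.getLogger("ambiscan")


@dataclass
class RunConfig:
    """Every stage parameter with its documented default; round-trips via YAML."""

    fasta: Optional[str] = None
    structure_file: Optional[str] = None
    band_matrix: Optional[str] = None
    out_dir: str = "ambiscan_out"

    run_scan: bool = True
    run_haplotypes: bool = True
    run_codons: bool = False
    run_structure: bool = False
    run_cluster: bool = False

    max_gap: int = 10
    min_block_sites: int = 2
    distance_model: str = "expected_mismatch"
    otu_threshold: float = 0.97
    enumeration_cap: int = 2 ** 20
    orf_start: int = 1
    code_table: str = "standard"
    coefficient: str = "dice"
    min_band_size: Optional[float] = None
    report_precision: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _rounded(x, precision):
    return round(x, precision) if isinstance(x, float) else x


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and write a report bundle under ``out_dir``.

    Returns the summary dictionary that is also written to ``summary.json``.
    Any stage failure raises with the stage name; outputs of completed
    stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {"version": __version__, "config_sha256": config.digest()},
        "parameters": dataclasses.asdict(config),
    }
    seqs = None
    records = None

    try:
        if config.run_scan or config.run_haplotypes or config.run_codons or config.run_structure:
            if not config.fasta:
                raise ValueError("a FASTA input is required for sequence stages")
            seqs = read_fasta(config.fasta, coordinate_offset=config.orf_start)
            log.info("read %d sequences from %s", len(seqs), config.fasta)

        if config.run_scan:
            records, census = scan_alignment(seqs)
            blocks = detect_blocks(
                records, max_gap=config.max_gap, min_block_sites=config.min_block_sites
            )
            write_sites_tsv(records, out / "sites.tsv")
            write_census_json(census, out / "census.json")
            summary["census"] = census.as_dict()
            summary["blocks"] = [dataclasses.asdict(b) for b in blocks]

        if config.run_haplotypes:
            haplo_summaries = {}
            for s in seqs:
                space = enumerate_haplotypes(s, cap=config.enumeration_cap)
                report = otu_split(s, config.otu_threshold)
                haplo_summaries[s.id] = {
                    "n_ambiguous_sites": space.n_ambiguous_sites,
                    "n_haplotypes": space.n_haplotypes,
                    "min_allele_count": space.min_allele_count,
                    "max_pairwise_divergence": _rounded(
                        space.max_pairwise_divergence, config.report_precision
                    ),
                    "otu_splits": report.splits,
                    "otu_margin": _rounded(report.margin, config.report_precision),
                }
                if space.haplotypes is not None and len(space.haplotypes) <= 64:
                    write_fasta(
                        [
                            (f"{s.id}_h{i + 1}", h)
                            for i, h in enumerate(space.haplotypes)
                        ],
                        out / f"haplotypes_{s.id}.fasta",
                    )
            summary["haplotypes"] = haplo_summaries

        if config.run_codons:
            frame = CodingFrame(
                orf_start_position=config.orf_start, code_table=config.code_table
            )
            table = summarize_coding(seqs, frame)
            summary["codons"] = {
                "n_codons_total": table.n_codons_total,
                "n_affected_union": table.n_affected_union,
                "n_affected_per_sequence": table.n_affected_per_sequence,
                "n_synonymous_union": table.n_synonymous_union,
                "pct_affected": _rounded(table.pct_affected, config.report_precision),
                "third_position_fraction": _rounded(
                    table.third_position_fraction, config.report_precision
                )
                if table.third_position_fraction is not None
                else None,
            }
            import pandas as pd

            pd.DataFrame(
                {
                    "codon_index": [e.codon_index for e in table.effects],
                    "codon": [e.codon for e in table.effects],
                    "resolutions": ["|".join(e.resolutions) for e in table.effects],
                    "amino_acids": ["".join(sorted(e.amino_acids)) for e in table.effects],
                    "effect": [e.effect for e in table.effects],
                }
            ).to_csv(out / "codon_effects.tsv", sep="\t", index=False)

        if config.run_structure:
            if not config.structure_file:
                raise ValueError("a Vienna structure file is required for the structure stage")
            struct_seq, struct = read_vienna(config.structure_file)
            if records is None:
                records, _ = scan_alignment(seqs)
            variable = [r.position for r in records if len(r.observed) > 1]
            ctx = site_context(struct, variable, seq=struct_seq)
            summary["structure"] = {
                "n_variable_sites": len(variable),
                "loop_fraction": ctx.loop_fraction_of_variable_sites,
                "wobble_neutral_fraction": ctx.wobble_neutral_fraction,
                "wobble_neutral_fraction_strict": ctx.wobble_neutral_fraction_strict,
            }

        if config.run_cluster:
            if not config.band_matrix:
                raise ValueError("a band-matrix CSV/TSV is required for the cluster stage")
            matrix = read_band_matrix(config.band_matrix)
            if config.min_band_size is not None:
                matrix = filter_bands(matrix, config.min_band_size)
            dm = distance_matrix(matrix, coefficient=config.coefficient)
            dm.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t")
            tree = upgma(dm)
            (out / "dendrogram.nwk").write_text(tree.newick + "\n")
            patterns = distinct_patterns(matrix)
            summary["cluster"] = {
                "n_strains": len(matrix.strain_ids),
                "n_bands": len(matrix.band_ids),
                "n_patterns": patterns.n_patterns,
                "undistinguishable_pairs": [
                    list(p) for p in patterns.undistinguishable_pairs
                ],
                "newick": tree.newick,
            }
    except Exception as exc:  # annotate with the failing stage context
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
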