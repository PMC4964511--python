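"""End-to-end orchestration: filter -> indices -> ENC/neutrality -> CA ->
optimal codons, with a manifest tying the outputs together.

Every stage writes a TSV into the output directory; the run manifest
(JSON) echoes the configuration and records a SHA-256 checksum per
artifact, so a rerun on identical input and configuration is verifiably
byte-identical. The default CAI reference set is the high-bias 5% subset
of the ENC-ratio ordering (self-contained); a user-supplied weight table
overrides it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .bias_indices import (
    ReferenceWeights,
    cai_weights,
    count_codons,
    pool_counts,
    profile_genes,
    rscu,
)
from .cds_io import CdsRecord, filter_cds, read_fasta, write_fasta
from .enc_neutrality import enc_ratio_histogram, neutrality_fit
from .genetic_code import standard_code, to_dna, to_rna
from .multivariate import build_rscu_matrix, correlation_report, correspondence_analysis
from .optimal_codons import optimal_codon_table, select_bias_subsets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input: str | Path
    output_dir: str | Path
    min_len_nt: int = 300
    subset_fraction: float = 0.05
    delta_rscu_threshold: float = 0.08
    correlation_method: str = "spearman"
    n_axes: int = 4
    cai_weights_path: str | Path | None = None
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subset_fraction < 0.5:
            raise ValueError("subset_fraction must lie in (0, 0.5)")
        if self.delta_rscu_threshold <= 0:
            raise ValueError("delta_rscu_threshold must be positive")
        if self.min_len_nt < 0:
            raise ValueError("min_len_nt must be non-negative")


@dataclass
class PipelineResult:
    outputs: dict[str, Path]
    manifest_path: Path
    n_genes: int
    warnings: list[str] = field(default_factory=list)


def load_weights(path: str | Path) -> ReferenceWeights:
    """Read a codon<TAB>weight table (RNA or DNA codons)."""
    df = pd.read_csv(path, sep="\t")
    w = {to_dna(c): float(v) for c, v in zip(df["codon"], df["weight"])}
    return ReferenceWeights(w=w, source=str(path))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6f")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis on a CDS FASTA; see the module docstring."""
    code = standard_code()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    warnings: list[str] = []
    stage = "filter"
    try:
        records = read_fasta(config.input)
        kept, report = filter_cds(records, config.min_len_nt, code)
        if not kept:
            raise ValueError("no CDS survived filtering")
        outputs["filter_report"] = outdir / "filter_report.tsv"
        report.to_tsv(outputs["filter_report"])
        outputs["filtered_fasta"] = outdir / "filtered.fasta"
        write_fasta(kept, outputs["filtered_fasta"])

        stage = "indices"
        counts = {r.id: count_codons(r) for r in kept}
        profiles = profile_genes(kept, code)  # CAI filled in below
        n_undef_enc = int(profiles["enc"].isna().sum())
        if n_undef_enc:
            warnings.append(f"{n_undef_enc} gene(s) with undefined ENC")

        stage = "optimal_codons"
        subsets = select_bias_subsets(profiles["enc_ratio"], config.subset_fraction)
        high = pool_counts([counts[g] for g in subsets.high_ids])
        low = pool_counts([counts[g] for g in subsets.low_ids])
        optimal = optimal_codon_table(high, low, code, config.delta_rscu_threshold)
        outputs["optimal_codons"] = outdir / "optimal_codons.tsv"
        _write_tsv(optimal, outputs["optimal_codons"], index=False)

        stage = "cai"
        if config.cai_weights_path is not None:
            weights = load_weights(config.cai_weights_path)
        else:
            weights = cai_weights(
                high, code, source=f"top-{config.subset_fraction:.0%} high-bias subset"
            )
        outputs["cai_weights"] = outdir / "cai_weights.tsv"
        weights.to_tsv(outputs["cai_weights"])
        profiles = profile_genes(kept, code, weights=weights)
        outputs["gene_indices"] = outdir / "gene_indices.tsv"
        _write_tsv(profiles, outputs["gene_indices"])

        stage = "pooled_rscu"
        pooled = pool_counts(list(counts.values()))
        pooled_rscu = rscu(pooled, code, include_stops=True)
        fam = {**code.families, "*": tuple(sorted(code.stop_codons))}
        rows = [
            {
                "amino_acid": aa,
                "codon": to_rna(c),
                "total_count": pooled[c],
                "rscu": pooled_rscu.values[c],
            }
            for aa, codons in fam.items()
            for c in codons
        ]
        outputs["rscu_pooled"] = outdir / "rscu_pooled.tsv"
        _write_tsv(pd.DataFrame(rows), outputs["rscu_pooled"], index=False)

        stage = "enc_neutrality"
        enc_table = profiles[["gc3s", "enc", "enc_exp", "enc_ratio"]]
        outputs["enc_table"] = outdir / "enc_table.tsv"
        _write_tsv(enc_table, outputs["enc_table"])
        fit = neutrality_fit(list(zip(profiles["gc3"], profiles["gc12"])))
        outputs["neutrality"] = outdir / "neutrality.tsv"
        fit.to_tsv(outputs["neutrality"])
        dist = enc_ratio_histogram(profiles["enc_ratio"].dropna().to_dict())

        stage = "correspondence_analysis"
        matrix = build_rscu_matrix(counts, code)
        n_imputed = int(matrix.imputed.any(axis=1).sum())
        if n_imputed:
            warnings.append(f"{n_imputed} gene(s) with imputed RSCU families")
        coa = correspondence_analysis(matrix, config.n_axes)
        outputs["coa_genes"] = outdir / "coa_gene_coordinates.tsv"
        _write_tsv(coa.row_coordinates, outputs["coa_genes"])
        outputs["coa_codons"] = outdir / "coa_codon_coordinates.tsv"
        codon_coords = coa.column_coordinates.copy()
        codon_coords.index = [to_rna(c) for c in codon_coords.index]
        _write_tsv(codon_coords, outputs["coa_codons"])
        outputs["coa_inertia"] = outdir / "coa_inertia.tsv"
        _write_tsv(
            pd.DataFrame(
                {
                    "inertia": coa.inertia,
                    "share": coa.inertia_share,
                },
                index=coa.row_coordinates.columns,
            ),
            outputs["coa_inertia"],
        )

        stage = "correlation"
        corr = correlation_report(profiles, coa, config.correlation_method)
        outputs["correlations"] = outdir / "correlations.tsv"
        _write_tsv(corr.render(), outputs["correlations"])

        if config.make_plots:
            stage = "plots"
            from . import plots

            outputs["enc_plot"] = outdir / "enc_plot.png"
            plots.enc_plot(profiles, outputs["enc_plot"])
            outputs["neutrality_plot"] = outdir / "neutrality_plot.png"
            plots.neutrality_plot(profiles, fit, outputs["neutrality_plot"])
            outputs["enc_ratio_hist"] = outdir / "enc_ratio_hist.png"
            plots.enc_ratio_hist_plot(dist, outputs["enc_ratio_hist"])
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise

    manifest = {
        "package": "codonbias",
        "version": __version__,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "n_genes": len(kept),
        "warnings": warnings,
        "artifacts": {
            name: {"path": p.name, "sha256": _sha256(p)} for name, p in outputs.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        outputs=outputs,
        manifest_path=manifest_path,
        n_genes=len(kept),
        warnings=warnings,
    )
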