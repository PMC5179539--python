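"""End-to-end orchestration of the five inference phases.

A single config drives: (A) method comparison by cross-validated AUC,
(B) per-regulator target prediction with the chosen model, (C) correlation
filtering and k-means clustering of known plus predicted targets,
(D) promoter scanning for direct/indirect classification, and (E) the
secondary-TF cascade.  All phase outputs are TSV files plus a JSON manifest
echoing seeds, thresholds and per-phase row counts; identical config and
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data_io import (
    CountMatrix,
    read_expression_table,
    read_gff3_genes,
    read_regulons,
)
from .diffexpr import de_genes_from_counts
from .evaluation import compare_methods
from .grn_svm import KernelSpec, predict_targets, train_regulator_models
from .motif import (
    classify_targets,
    extract_promoters,
    read_meme_motifs,
    scan_promoters,
    secondary_cascade,
)
from .postprocess import (
    assemble_network,
    correlation_filter,
    correlation_table,
    kmeans_cluster,
)

log = logging.getLogger("beacongrn")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression: str
    regulons: str
    out_dir: str
    counts: str | None = None
    design: str | None = None
    de_genes: str | None = None
    genome: str | None = None
    gff: str | None = None
    motifs: str | None = None
    regulator_motifs: dict[str, str] = field(default_factory=dict)
    tf_list: list[str] = field(default_factory=list)
    mode: str = "local"
    kernel: str = "rbf"
    C: float = 1000.0
    gamma: float | None = None
    epsilon: float = 1.0
    seed: int = 17
    alpha_de: float = 0.05
    r_threshold: float = 0.6
    p_motif: float = 1e-4
    clr_bins: int | None = None
    k_clusters: dict[str, int] = field(default_factory=dict)
    default_k: int = 3
    run_comparison: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_de < 1 or not 0 < self.p_motif < 1:
            raise ValueError("alpha_de and p_motif must be in (0, 1)")
        if not -1 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must be in [-1, 1]")
        for name in ("expression", "regulons"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _load_de_genes(config: PipelineConfig) -> tuple[set[str], str]:
    if config.de_genes:
        with open(config.de_genes) as fh:
            return {l.strip() for l in fh if l.strip()}, "file"
    if config.counts and config.design:
        counts = CountMatrix.from_tsv(config.counts, config.design)
        de, _ = de_genes_from_counts(counts, alpha=config.alpha_de)
        return de, "computed"
    raise ValueError("provide either de_genes or counts+design")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute phases A-E; returns the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            "mode": config.mode, "kernel": config.kernel, "C": config.C,
            "gamma": config.gamma, "epsilon": config.epsilon, "seed": config.seed,
            "alpha_de": config.alpha_de, "r_threshold": config.r_threshold,
            "p_motif": config.p_motif, "clr_bins": config.clr_bins,
        },
        "phases": {},
        "complete": False,
    }
    phase = "load"
    try:
        expression = read_expression_table(config.expression)
        regulons = read_regulons(config.regulons)
        de_genes, de_source = _load_de_genes(config)
        de_genes &= set(expression.gene_ids)
        manifest["phases"]["load"] = {
            "n_genes": expression.n_genes,
            "n_regulators": len(regulons),
            "n_de_genes": len(de_genes),
            "de_source": de_source,
        }
        known = {r: regulons.targets(r) for r in regulons}
        kernel = KernelSpec(config.kernel, gamma=config.gamma)

        phase = "A_comparison"
        if config.run_comparison:
            report = compare_methods(
                expression, known, de_genes, seed=config.seed, C=config.C,
                n_bins=config.clr_bins, epsilon=config.epsilon,
            )
            report.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["phases"]["A_comparison"] = {"rows": len(report)}
            log.info("phase A: %d report rows", len(report))

        phase = "B_prediction"
        models = train_regulator_models(
            expression, known, mode=config.mode, kernel=kernel, C=config.C,
            seed=config.seed, epsilon=config.epsilon,
        )
        predicted = predict_targets(models, de_genes, expression)
        edge_rows = [
            {"regulator": r, "target": t, "score": f"{s:.6g}", "predicted_class": 1}
            for r in sorted(predicted)
            for t, s in sorted(predicted[r].items())
        ]
        pd.DataFrame(edge_rows, columns=["regulator", "target", "score", "predicted_class"]).to_csv(
            out / "edges.tsv", sep="\t", index=False
        )
        manifest["phases"]["B_prediction"] = {
            r: len(predicted[r]) for r in sorted(predicted)
        }
        log.info("phase B: predicted targets per regulator %s", manifest["phases"]["B_prediction"])

        phase = "C_clustering"
        all_targets = {
            r: (set(predicted.get(r, {})) | known.get(r, set())) & set(expression.gene_ids)
            for r in sorted(known)
        }
        corr = correlation_table(expression, all_targets)
        retained = correlation_filter(corr, config.r_threshold)
        clusters = {}
        cluster_rows = []
        for reg in sorted(retained):
            genes = sorted(retained[reg])
            k = config.k_clusters.get(reg, config.default_k)
            if len(genes) < max(k, 2):
                continue
            ca = kmeans_cluster(
                expression.subset(genes), k, seed=config.seed, known_genes=known.get(reg, set())
            )
            clusters[reg] = ca
            for g in genes:
                cluster_rows.append(
                    {
                        "regulator": reg, "gene": g, "cluster": ca.assignment[g],
                        "known": int(ca.known_flags[g]),
                    }
                )
        pd.DataFrame(cluster_rows, columns=["regulator", "gene", "cluster", "known"]).to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
        manifest["phases"]["C_clustering"] = {
            "retained": {r: len(retained[r]) for r in sorted(retained)},
            "clustered_regulators": sorted(clusters),
        }

        phase = "D_direct_targets"
        classifications = {}
        hits_rows = []
        scan_possible = bool(config.genome and config.gff and config.motifs)
        if scan_possible:
            motifs = {m.motif_id: m for m in read_meme_motifs(config.motifs)}
            annotations = read_gff3_genes(config.gff)
            import pyfaidx

            genome = pyfaidx.Fasta(config.genome)
            for reg in sorted(clusters):
                motif_id = config.regulator_motifs.get(reg)
                targets = set(retained[reg])
                if motif_id is None or motif_id not in motifs:
                    classifications[reg] = classify_targets(
                        reg, targets, [], {}, alpha=config.p_motif
                    )
                    continue
                annotated = {a.gene_id for a in annotations}
                promoters, _skipped = extract_promoters(
                    genome, annotations, sorted(targets & annotated)
                )
                hits = scan_promoters(promoters, [motifs[motif_id]], config.p_motif)
                for h in hits:
                    hits_rows.append(
                        {
                            "regulator": reg, "gene": h.gene_id, "motif": h.motif_id,
                            "start": h.start, "strand": h.strand,
                            "score": f"{h.score:.6g}", "p_value": f"{h.p_value:.6g}",
                        }
                    )
                classifications[reg] = classify_targets(
                    reg, targets, hits, promoters, motif_ids={motif_id}, alpha=config.p_motif
                )
                phase = "E_secondary"
                secondary_cascade(
                    classifications[reg], config.tf_list,
                    {r: motifs[m] for r, m in config.regulator_motifs.items() if m in motifs},
                    promoters, alpha=config.p_motif,
                )
                phase = "D_direct_targets"
        pd.DataFrame(
            hits_rows,
            columns=["regulator", "gene", "motif", "start", "strand", "score", "p_value"],
        ).to_csv(out / "hits.tsv", sep="\t", index=False)
        manifest["phases"]["D_direct_targets"] = {
            "scanned": scan_possible,
            "summary": {
                r: {
                    "direct": len(c.direct),
                    "indirect": len(c.indirect),
                    "unscanned": len(c.unscanned),
                    "secondary_tfs": sorted(c.secondary),
                }
                for r, c in sorted(classifications.items())
            },
        }
        if not scan_possible:
            manifest["phases"]["D_direct_targets"]["skipped_reason"] = (
                "genome/gff/motifs not configured"
            )

        phase = "network"
        direct_status = {}
        for reg in sorted(known):
            status = {}
            c = classifications.get(reg)
            if c is not None:
                for t in c.direct:
                    status[t] = "direct"
                for t in c.indirect:
                    status[t] = "indirect"
            direct_status[reg] = status
        network = assemble_network(
            predicted={r: set(predicted.get(r, {})) for r in sorted(known)},
            known=known,
            correlations=corr,
            clusters=clusters,
            direct_status=direct_status,
        )
        network.to_tsv(out / "network.tsv")
        manifest["phases"]["network"] = {"edges": len(network.edges)}
        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_phase"] = phase
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"pipeline failed in phase {phase}: {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
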