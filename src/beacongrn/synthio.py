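"""Seeded synthetic data: every input the inference pipeline consumes.

The generator emulates the shape of an embryo-development RNA-seq series:
seven timepoints, three replicates, FPKM-like profiles, a transcription
factor with a planted regulon of coupled targets, negative-binomial counts,
and promoter sequences with planted binding sites.  Planted structure is
returned alongside the data so recovery tests can score the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .data_io import CountMatrix, ExpressionMatrix, GeneAnnotation, RegulonSet
from .motif import PWM, write_meme_motifs

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_counts",
    "simulate_de_counts",
    "simulate_promoters",
    "demo_pwm",
    "write_fixtures",
]

DEFAULT_TIMEPOINTS = ["7", "8", "10", "12", "13", "15", "17"]  # days after pollination


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 500 genes, one regulator with 100 targets,
    coupling 1.0, noise sd at 25% of the regulator signal sd, 7 timepoints
    with 3 replicates, NB dispersion 0.1."""

    n_genes: int = 500
    n_regulators: int = 1
    regulon_size: int = 100
    k_timepoints: int = 7
    n_replicates: int = 3
    coupling: float = 1.0
    noise_sd: float = 0.25           # fraction of the regulator profile's sd
    fraction_negative_coupling: float = 0.0
    dispersion: float = 0.1          # NB: var = mu + dispersion * mu^2
    count_scale: float = 50.0        # counts per FPKM unit
    motif_length: int = 10
    planting_rate: float = 1.0
    mutation_rate: float = 0.0       # per-position mutations of planted sites
    promoter_length: int = 500
    seed: int = 17

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_genes", "n_regulators", "regulon_size", "k_timepoints",
                     "n_replicates", "motif_length", "promoter_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("fraction_negative_coupling", "planting_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_regulators * self.regulon_size > self.n_genes - self.n_regulators:
            raise ValueError("regulons larger than the available gene pool")

    def timepoint_labels(self) -> list[str]:
        if self.k_timepoints == 7:
            return list(DEFAULT_TIMEPOINTS)
        return [str(t) for t in range(1, self.k_timepoints + 1)]


def _smooth_curve(rng: np.random.Generator, k: int, base: float = 1.0, amp: float = 9.0) -> np.ndarray:
    """A cubic-smoothed random curve over k points, scaled into [base, base+amp]."""
    n_knots = 4
    knots = np.linspace(0, k - 1, n_knots)
    vals = rng.uniform(0.0, 1.0, size=n_knots)
    curve = CubicSpline(knots, vals)(np.arange(k))
    lo, hi = curve.min(), curve.max()
    if hi > lo:
        curve = (curve - lo) / (hi - lo)
    else:
        curve = np.zeros(k)
    return base + amp * curve


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, RegulonSet, dict[str, dict[str, int]]]:
    """Expression matrix with planted regulons.

    Regulator profiles are smooth random curves; each true target is
    ``coupling * regulator + noise`` (sign-flipped around the profile's
    midline for the negative-coupling fraction); all other genes are
    independent smooth curves.  Values are clipped at zero.

    Returns (matrix, true regulons, coupling signs per regulator/target).
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_timepoints
    regulators = [f"TF{i+1}" for i in range(config.n_regulators)]
    n_targets_total = config.n_regulators * config.regulon_size
    others = [f"G{i+1:05d}" for i in range(config.n_genes - config.n_regulators)]
    target_pool = others[:n_targets_total]

    profiles: dict[str, np.ndarray] = {}
    regulons = RegulonSet()
    signs: dict[str, dict[str, int]] = {}
    cursor = 0
    for reg in regulators:
        reg_profile = _smooth_curve(rng, k)
        profiles[reg] = reg_profile
        signal_sd = reg_profile.std()
        noise = config.noise_sd * signal_sd
        signs[reg] = {}
        targets = target_pool[cursor : cursor + config.regulon_size]
        cursor += config.regulon_size
        n_neg = int(round(config.fraction_negative_coupling * len(targets)))
        for i, t in enumerate(targets):
            eps = rng.normal(0.0, noise, size=k) if noise > 0 else 0.0
            if i < n_neg:
                mirrored = config.coupling * (reg_profile.max() + reg_profile.min() - reg_profile)
                profiles[t] = np.clip(mirrored + eps, 0.0, None)
                signs[reg][t] = -1
            else:
                profiles[t] = np.clip(config.coupling * reg_profile + eps, 0.0, None)
                signs[reg][t] = 1
            regulons.add(reg, t)
    for g in others[n_targets_total:]:
        noise = config.noise_sd * 1.0
        base = _smooth_curve(rng, k)
        eps = rng.normal(0.0, noise, size=k) if noise > 0 else 0.0
        profiles[g] = np.clip(base + eps, 0.0, None)

    gene_ids = regulators + others
    values = np.array([profiles[g] for g in gene_ids])
    matrix = ExpressionMatrix(gene_ids, config.timepoint_labels(), values)
    return matrix, regulons, signs


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(expression: ExpressionMatrix, config: SimulationConfig) -> CountMatrix:
    """Replicate-level NB counts with mean proportional to expression."""
    rng = np.random.default_rng(config.seed + 1)
    samples = [
        (t, f"rep{r+1}")
        for t in expression.timepoints
        for r in range(config.n_replicates)
    ]
    counts = np.zeros((expression.n_genes, len(samples)), dtype=np.int64)
    col = 0
    for ti in range(expression.n_timepoints):
        for _ in range(config.n_replicates):
            mu = expression.values[:, ti] * config.count_scale
            counts[:, col] = _nb_draw(rng, mu, config.dispersion)
            col += 1
    return CountMatrix(expression.gene_ids, samples, counts)


def simulate_de_counts(
    n_genes: int = 1000,
    n_de: int = 100,
    effect_sd: float = 4.0,
    k_timepoints: int = 7,
    n_replicates: int = 3,
    base_mean: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 17,
) -> tuple[CountMatrix, set[str]]:
    """Count matrix with planted expression shifts for power studies.

    Null genes keep a constant mean across the series; each planted gene
    shifts its mean at one random consecutive boundary by ``effect_sd``
    per-observation standard deviations on the log2 scale.  Returns the
    counts and the set of truly shifted gene ids.
    """
    rng = np.random.default_rng(seed)
    labels = (
        DEFAULT_TIMEPOINTS if k_timepoints == 7 else [str(t) for t in range(1, k_timepoints + 1)]
    )
    genes = [f"G{i+1:05d}" for i in range(n_genes)]
    true_de = set(genes[:n_de])
    obs_sd_log2 = np.sqrt(1.0 / base_mean + dispersion) / np.log(2.0)
    shift_log2 = effect_sd * obs_sd_log2
    samples = [(t, f"rep{r+1}") for t in labels for r in range(n_replicates)]
    means = np.full((n_genes, k_timepoints), base_mean)
    base = base_mean * rng.lognormal(0.0, 0.25, size=n_genes)
    means = np.repeat(base[:, None], k_timepoints, axis=1)
    for gi in range(n_de):
        boundary = rng.integers(1, k_timepoints)
        direction = rng.choice([-1.0, 1.0])
        means[gi, boundary:] *= 2.0 ** (direction * shift_log2)
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for col, (t, _) in enumerate(samples):
        ti = labels.index(t)
        counts[:, col] = _nb_draw(rng, means[:, ti], dispersion)
    return CountMatrix(genes, samples, counts), true_de


def demo_pwm(length: int = 10, seed: int = 17, sharpness: float = 0.91) -> PWM:
    """A sharp synthetic PWM with a random consensus (for planting/recovery)."""
    rng = np.random.default_rng(seed)
    probs = np.full((length, 4), (1.0 - sharpness) / 3.0)
    consensus = rng.integers(0, 4, size=length)
    probs[np.arange(length), consensus] = sharpness
    return PWM(f"SYN{seed}", probs)


def simulate_promoters(
    true_regulons: RegulonSet,
    pwm: PWM,
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneAnnotation], set[str]]:
    """Random promoters with the PWM consensus planted in a fraction of targets.

    All target genes are laid head-to-tail on one forward-strand chromosome
    so each gene's upstream region is exactly ``promoter_length`` bp and
    bounded by its upstream neighbour.  The consensus (with per-position
    mutations at ``mutation_rate``) is planted at a random offset in
    ``planting_rate`` of the targets.  Returns ({chrom: sequence},
    annotations, planted gene ids).
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = sorted({t for _, targets in true_regulons.items() for t in targets})
    consensus = pwm.consensus
    L = len(consensus)
    if L > config.promoter_length:
        raise ValueError("motif longer than the promoter")
    planted: set[str] = set()
    gene_body = 200
    chrom_parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 0  # 0-based running coordinate
    for g in genes:
        promoter = rng.choice(list("ACGT"), size=config.promoter_length)
        if rng.random() < config.planting_rate:
            site = list(consensus)
            for i in range(L):
                if rng.random() < config.mutation_rate:
                    site[i] = rng.choice([b for b in "ACGT" if b != site[i]])
            off = rng.integers(0, config.promoter_length - L + 1)
            promoter[off : off + L] = list("".join(site))
            planted.add(g)
        body = rng.choice(list("ACGT"), size=gene_body)
        chrom_parts.append("".join(promoter) + "".join(body))
        start = pos + config.promoter_length + 1          # 1-based gene start
        annotations.append(GeneAnnotation(g, "chrS", "+", start, start + gene_body - 1))
        pos += config.promoter_length + gene_body
    return {"chrS": "".join(chrom_parts)}, annotations, planted


def write_gff3(annotations: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.chrom}\tsynthio\tgene\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t"
                f"ID={a.gene_id}\n"
            )


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fixtures(config: SimulationConfig, outdir) -> dict[str, object]:
    """Emit the full fixture bundle (TSV/FASTA/GFF3/MEME) plus truth objects."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, regulons, signs = simulate_expression(config)
    counts = simulate_counts(expr, config)
    pwm = demo_pwm(config.motif_length, config.seed)
    genome, annotations, planted = simulate_promoters(regulons, pwm, config)

    expr.to_tsv(outdir / "expr.tsv")
    counts.to_tsv(outdir / "counts.tsv", outdir / "design.tsv")
    regulons.to_tsv(outdir / "regulons.tsv")
    write_fasta(genome, outdir / "genome.fa")
    write_gff3(annotations, outdir / "genes.gff3")
    write_meme_motifs([pwm], outdir / "motifs.meme")
    truth = {
        "regulons": {r: sorted(t) for r, t in regulons.items()},
        "coupling_signs": signs,
        "planted_motif_genes": sorted(planted),
        "motif_id": pwm.motif_id,
        "seed": config.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {
        "expression": expr,
        "counts": counts,
        "regulons": regulons,
        "signs": signs,
        "pwm": pwm,
        "genome": genome,
        "annotations": annotations,
        "planted": planted,
    }
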