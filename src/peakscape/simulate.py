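"""Synthetic miniature dataset generator.

Produces a small multi-chromosome genome with sequence, gene/tRNA/ncRNA
annotations, per-subunit/replicate ChIP coverage tracks with planted peaks,
matched input tracks, expression and differential-expression tables, TF peak
sets and HOT regions — together with the full ground truth, so every
downstream stage has a parameter-recovery oracle.  Fully deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from peakscape.core import (
    GENE,
    NCRNA_LONG,
    NCRNA_SHORT,
    TRNA,
    AnnotationRecord,
    AnnotationSet,
    CoverageTrack,
    GenomeModel,
    Interval,
    Peak,
    PeakSet,
    write_fasta,
    write_gff,
    write_peaks,
    write_track,
)
from peakscape.consensus import consensus_k_of_n

COMPLEXES = ("condensin_IDC", "condensin_II")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.  Defaults give a 1.2 Mb, 6-chromosome toy."""

    n_chroms: int = 6
    chrom_length: int = 200_000
    n_genes_per_chrom: int = 50
    n_trnas_per_chrom: int = 6
    n_ncrnas_per_chrom: int = 6
    frac_active_promoters_bound: float = 0.25
    trna_bound_prob: float = 0.5
    n_enhancers_per_complex: int = 30
    x_bias: float = 30.0
    peak_width_mean: float = 400.0
    peak_width_sd: float = 80.0
    enrichment_height: float = 8.0
    background_rate: float = 10.0
    gc_background: float = 0.36
    gc_at_peaks: float = 0.60
    gc_elevation_halfwidth: int = 100
    motif_consensus: str = "GCGCAGGGCG"
    motif_plant_prob: float = 0.6
    expression_mu: float = 2.0
    expression_sigma: float = 1.0
    expression_shift: float = 1.0
    expression_target_spearman: float | None = None
    n_expression_replicates: int = 5
    n_subunits: int = 3
    n_replicates: int = 3
    replicate_noise: float = 1.0
    replicate_dropout: float = 0.0
    n_tfs: int = 5
    tf_overlap_rate: float = 0.6
    tf_n_sites: int = 80
    hot_k: int = 3
    frac_de_genes: float = 0.1
    de_up_bias_bound: float = 0.8
    de_up_bias_unbound: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_active_promoters_bound",
            "trna_bound_prob",
            "motif_plant_prob",
            "replicate_dropout",
            "tf_overlap_rate",
            "frac_de_genes",
            "de_up_bias_bound",
            "de_up_bias_unbound",
            "gc_background",
            "gc_at_peaks",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_rate <= 0 or self.enrichment_height < 0:
            raise ValueError("rates/heights must be non-negative (background > 0)")
        if self.chrom_length < 10 * self.peak_width_mean:
            raise ValueError("chrom_length must be at least 10x the mean peak width")


@dataclass
class SimulatedBundle:
    """Everything the generator produced, data and ground truth together."""

    config: SimulationConfig
    genome: GenomeModel
    sequences: dict[str, str]
    annotations: AnnotationSet
    active_genes: set[str]
    true_peaks: dict[str, PeakSet]
    peak_strengths: dict[str, np.ndarray]
    chip_tracks: dict[str, dict[str, list[CoverageTrack]]]  # complex -> subunit -> reps
    input_tracks: dict[str, CoverageTrack]
    dropped: dict[str, set[tuple[str, int, int]]]  # (subunit, replicate, peak idx)
    expression: pd.DataFrame
    bound_genes: set[str]
    de_table: pd.DataFrame
    tf_sets: dict[str, list[Interval]]
    tf_truth_overlap: dict[str, float]
    hot_regions: list[Interval]
    planted_motifs: list[Interval]

    def subunit_names(self, complex_name: str) -> list[str]:
        return sorted(self.chip_tracks[complex_name])


def _chrom_names(n: int) -> list[str]:
    if n < 2:
        raise ValueError("need at least 2 chromosomes (one autosome plus X)")
    return [f"chr{i + 1}" for i in range(n - 1)] + ["chrX"]


def generate_genome_model(config: SimulationConfig) -> GenomeModel:
    names = _chrom_names(config.n_chroms)
    return GenomeModel({c: config.chrom_length for c in names}, x_chrom="chrX")


def generate_annotations(
    config: SimulationConfig, genome: GenomeModel, rng: np.random.Generator
) -> tuple[AnnotationSet, set[str]]:
    """Non-overlapping gene-like records on an evenly slotted layout, plus the
    'active' gene subset (higher baseline expression, eligible for binding)."""
    records: list[AnnotationRecord] = []
    active: set[str] = set()
    for chrom in genome.chrom_names:
        n_feat = config.n_genes_per_chrom + config.n_trnas_per_chrom + config.n_ncrnas_per_chrom
        slot = genome.length(chrom) // (n_feat + 1)
        kinds = (
            [GENE] * config.n_genes_per_chrom
            + [TRNA] * config.n_trnas_per_chrom
            + ["ncRNA"] * config.n_ncrnas_per_chrom
        )
        rng.shuffle(kinds)
        for i, kind in enumerate(kinds):
            anchor = (i + 1) * slot
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == GENE:
                length = int(rng.integers(800, min(3000, slot - 10)))
                cls = GENE
            elif kind == TRNA:
                length = int(rng.integers(70, 90))
                cls = TRNA
            else:
                if rng.random() < 0.5:
                    length = int(rng.integers(50, 200))
                    cls = NCRNA_SHORT
                else:
                    length = int(rng.integers(201, min(1500, slot - 10)))
                    cls = NCRNA_LONG
            start = anchor
            end = min(start + length, genome.length(chrom))
            name = f"{cls}_{chrom}_{i + 1}"
            records.append(AnnotationRecord(chrom, start, end, strand, cls, name))
            if cls == GENE and rng.random() < 0.5:
                active.add(name)
    return AnnotationSet(records, genome=genome), active


def generate_true_peaks(
    config: SimulationConfig,
    genome: GenomeModel,
    annotations: AnnotationSet,
    active_genes: set[str],
    rng: np.random.Generator,
) -> tuple[dict[str, PeakSet], dict[str, np.ndarray], set[str]]:
    """Plant peaks at a fraction of active promoters, at tRNAs and at intergenic
    'enhancer' positions.

    ``x_bias`` multiplies the binding density of the IDC complex on the X:
    promoter/tRNA binding probabilities are scaled by it (capped at 1) and
    enhancer chromosomes are drawn with weight proportional to
    length * x_bias.  Returns per-complex PeakSets, aligned summit-strength
    multipliers, and the set of genes whose promoter received a peak.
    """
    genes = [r for r in annotations if r.cls == GENE]
    trnas = [r for r in annotations if r.cls == TRNA]
    bound_genes: set[str] = set()
    true_peaks: dict[str, PeakSet] = {}
    strengths: dict[str, np.ndarray] = {}
    for complex_name in COMPLEXES:
        is_idc = complex_name == "condensin_IDC"

        def xw(chrom: str) -> float:
            return config.x_bias if (is_idc and chrom == genome.x_chrom) else 1.0

        sites: list[tuple[str, int, str]] = []
        for g in genes:
            if g.name not in active_genes:
                continue
            if rng.random() < min(1.0, config.frac_active_promoters_bound * xw(g.chrom)):
                sites.append((g.chrom, g.tss, g.name))
                bound_genes.add(g.name)
        for t in trnas:
            if rng.random() < min(1.0, config.trna_bound_prob * xw(t.chrom)):
                sites.append((t.chrom, (t.start + t.end) // 2, t.name))
        chrom_w = np.array([genome.length(c) * xw(c) for c in genome.chrom_names])
        for _ in range(config.n_enhancers_per_complex):
            ci = int(rng.choice(len(chrom_w), p=chrom_w / chrom_w.sum()))
            chrom = genome.chrom_names[ci]
            pos = int(rng.integers(2000, genome.length(chrom) - 2000))
            sites.append((chrom, pos, "enhancer"))

        pairs: list[tuple[Peak, float]] = []
        for chrom, pos, label in sites:
            width = max(60, int(rng.normal(config.peak_width_mean, config.peak_width_sd)))
            start = max(0, pos - width // 2)
            end = min(genome.length(chrom), start + width)
            summit = min(max(pos, start), end - 1)
            pairs.append(
                (Peak(chrom, start, end, summit, 0.0, name=label),
                 float(np.exp(rng.normal(0.0, 0.5))))
            )
        # keep strengths aligned with PeakSet's (chrom, start, end) sort order
        pairs.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
        true_peaks[complex_name] = PeakSet([p for p, _ in pairs], genome=genome)
        strengths[complex_name] = np.array([s for _, s in pairs])
    return true_peaks, strengths, bound_genes


def generate_sequence(
    config: SimulationConfig,
    genome: GenomeModel,
    summits: list[tuple[str, int]],
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[Interval]]:
    """i.i.d. background sequence at ``gc_background``, GC elevated to
    ``gc_at_peaks`` within +/- ``gc_elevation_halfwidth`` of each summit, and
    the motif consensus planted at a fraction of summits.
    """
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def draw(length: int, gc: float) -> np.ndarray:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return bases[rng.choice(4, size=length, p=p)]

    seqs = {c: draw(genome.length(c), config.gc_background) for c in genome.chrom_names}
    half = config.gc_elevation_halfwidth
    for chrom, pos in summits:
        s, e = max(0, pos - half), min(genome.length(chrom), pos + half + 1)
        seqs[chrom][s:e] = draw(e - s, config.gc_at_peaks)
    planted: list[Interval] = []
    motif = np.frombuffer(config.motif_consensus.upper().encode(), dtype=np.uint8)
    for chrom, pos in summits:
        if rng.random() < config.motif_plant_prob:
            start = pos - len(motif) // 2
            if 0 <= start and start + len(motif) <= genome.length(chrom):
                seqs[chrom][start : start + len(motif)] = motif
                planted.append(Interval(chrom, start, start + len(motif), strand="+"))
    return {c: v.tobytes().decode("ascii") for c, v in seqs.items()}, planted


def _add_bump(arr: np.ndarray, summit: int, amp: float, sd: float) -> None:
    lo = max(0, int(summit - 4 * sd))
    hi = min(len(arr), int(summit + 4 * sd) + 1)
    x = np.arange(lo, hi)
    arr[lo:hi] += amp * np.exp(-((x - summit) ** 2) / (2 * sd**2))


def generate_binding_tracks(
    config: SimulationConfig,
    genome: GenomeModel,
    true_peaks: dict[str, PeakSet],
    strengths: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[
    dict[str, dict[str, list[CoverageTrack]]],
    dict[str, CoverageTrack],
    dict[str, set[tuple[str, int, int]]],
]:
    """Per-complex, per-subunit replicate ChIP tracks plus matched input tracks.

    Coverage = Poisson(background) + Gaussian bump per true peak (sd =
    width/4, amplitude = background * enrichment_height * per-peak strength)
    + i.i.d. Gaussian replicate noise.  With ``replicate_dropout`` > 0 a peak
    may be missing from a minority of a subunit's replicates.
    """
    chip: dict[str, dict[str, list[CoverageTrack]]] = {}
    inputs: dict[str, CoverageTrack] = {}
    dropped: dict[str, set[tuple[str, int, int]]] = {c: set() for c in true_peaks}
    prefix = {"condensin_IDC": "idcSub", "condensin_II": "iiSub"}
    for complex_name, peaks in true_peaks.items():
        chip[complex_name] = {}
        amp0 = config.background_rate * config.enrichment_height
        for s in range(config.n_subunits):
            subunit = f"{prefix.get(complex_name, complex_name)}{s + 1}"
            reps: list[CoverageTrack] = []
            # at most a minority of replicates may drop any given peak
            max_drop = (config.n_replicates - 1) // 2
            drop_count: dict[int, int] = {}
            for r in range(config.n_replicates):
                data = {}
                for chrom in genome.chrom_names:
                    arr = rng.poisson(config.background_rate, genome.length(chrom)).astype(float)
                    if config.replicate_noise > 0:
                        arr += rng.normal(0.0, config.replicate_noise, len(arr))
                    data[chrom] = arr
                for i, p in enumerate(peaks):
                    if (
                        config.replicate_dropout > 0
                        and drop_count.get(i, 0) < max_drop
                        and rng.random() < config.replicate_dropout
                    ):
                        drop_count[i] = drop_count.get(i, 0) + 1
                        dropped[complex_name].add((subunit, r, i))
                        continue
                    amp = amp0 * strengths[complex_name][i]
                    if amp > 0:
                        _add_bump(data[p.chrom], p.summit, amp, max(len(p) / 4.0, 10.0))
                reps.append(CoverageTrack(data, genome, state="raw"))
            chip[complex_name][subunit] = reps
        inp = {
            c: rng.poisson(config.background_rate, genome.length(c)).astype(float)
            for c in genome.chrom_names
        }
        inputs[complex_name] = CoverageTrack(inp, genome, state="raw")
    return chip, inputs, dropped


def generate_expression(
    config: SimulationConfig,
    annotations: AnnotationSet,
    bound_genes: set[str],
    active_genes: set[str],
    rng: np.random.Generator,
    binding_strength: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Log-normal per-gene expression with replicates.

    Default coupling: genes whose promoter carries a true peak get a
    ``expression_shift`` upward shift in log space.  When
    ``expression_target_spearman`` is set (and ``binding_strength`` given), a
    Gaussian copula couples expression to the binding-strength ranks so the
    planted Spearman correlation is recoverable.
    """
    genes = [r for r in annotations if r.cls == GENE]
    names = [g.name for g in genes]
    n = len(names)
    if config.expression_target_spearman is not None:
        if binding_strength is None:
            raise ValueError("copula coupling needs per-gene binding strengths")
        rho_s = config.expression_target_spearman
        rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        s = np.array([binding_strength.get(g, 0.0) for g in names])
        s = s + rng.normal(0, 1e-9, n)  # break ties so ranks are unambiguous
        from scipy.stats import norm, rankdata

        z = norm.ppf((rankdata(s)) / (n + 1))
        eps = rng.normal(0, 1, n)
        log_expr = config.expression_mu + config.expression_sigma * (
            rho_p * z + np.sqrt(1 - rho_p**2) * eps
        )
    else:
        base = np.where(
            [g in active_genes for g in names],
            config.expression_mu,
            config.expression_mu - 2.0,
        )
        log_expr = rng.normal(base, config.expression_sigma)
        log_expr += np.array([config.expression_shift if g in bound_genes else 0.0 for g in names])
    rows = {}
    for r in range(config.n_expression_replicates):
        rows[f"rep{r + 1}"] = np.exp(log_expr + rng.normal(0, 0.1, n))
    df = pd.DataFrame({"gene": names, **rows})
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    df["median"] = df[rep_cols].median(axis=1)
    return df


def generate_de_table(
    config: SimulationConfig,
    expression: pd.DataFrame,
    bound_genes: set[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Differential-expression result table with a planted up-bias for bound genes."""
    rows = []
    for gene in expression["gene"]:
        if rng.random() >= config.frac_de_genes:
            continue
        bias = config.de_up_bias_bound if gene in bound_genes else config.de_up_bias_unbound
        up = rng.random() < bias
        lfc = abs(rng.normal(1.0, 0.3)) * (1 if up else -1)
        rows.append(
            {"gene": gene, "lfc": lfc, "padj": float(rng.uniform(0, 0.05)),
             "direction": "up" if up else "down"}
        )
    return pd.DataFrame(rows, columns=["gene", "lfc", "padj", "direction"])


def generate_tf_sets(
    config: SimulationConfig,
    true_peaks: dict[str, PeakSet],
    genome: GenomeModel,
    rng: np.random.Generator,
) -> tuple[dict[str, list[Interval]], dict[str, float], list[Interval]]:
    """TF peak sets overlapping condensin truth at the configured rate, plus HOT
    regions (loci covered by >= hot_k TF sets)."""
    all_true = [p for ps in true_peaks.values() for p in ps]
    tf_sets: dict[str, list[Interval]] = {}
    truth_rates: dict[str, float] = {}
    for t in range(config.n_tfs):
        name = f"TF{t + 1}"
        sites = []
        n_at_truth = 0
        for _ in range(config.tf_n_sites):
            width = int(rng.integers(150, 350))
            if all_true and rng.random() < config.tf_overlap_rate:
                p = all_true[int(rng.integers(0, len(all_true)))]
                center = p.summit + int(rng.integers(-100, 101))
                chrom = p.chrom
                n_at_truth += 1
            else:
                chrom = genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
                center = int(rng.integers(width, genome.length(chrom) - width))
            s = max(0, center - width // 2)
            e = min(genome.length(chrom), s + width)
            sites.append(Interval(chrom, s, e, name=f"{name}_{len(sites) + 1}"))
        tf_sets[name] = sorted(sites, key=lambda iv: (iv.chrom, iv.start))
        truth_rates[name] = n_at_truth / config.tf_n_sites
    hot = consensus_k_of_n(list(tf_sets.values()), k=min(config.hot_k, config.n_tfs))
    return tf_sets, truth_rates, hot


def simulate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedBundle:
    """Run the full generator; ``seed`` overrides ``config.rng_seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    genome = generate_genome_model(config)
    annotations, active = generate_annotations(config, genome, rng)
    true_peaks, strengths, bound_genes = generate_true_peaks(
        config, genome, annotations, active, rng
    )
    summits = [(p.chrom, p.summit) for ps in true_peaks.values() for p in ps]
    sequences, planted_motifs = generate_sequence(config, genome, summits, rng)
    chip, inputs, dropped = generate_binding_tracks(config, genome, true_peaks, strengths, rng)
    binding_strength = {}
    for complex_name, ps in true_peaks.items():
        for i, p in enumerate(ps):
            if p.name and p.name.startswith(GENE):
                binding_strength[p.name] = (
                    binding_strength.get(p.name, 0.0) + float(strengths[complex_name][i])
                )
    expression = generate_expression(
        config, annotations, bound_genes, active, rng, binding_strength=binding_strength
    )
    de_table = generate_de_table(config, expression, bound_genes, rng)
    tf_sets, truth_rates, hot = generate_tf_sets(config, true_peaks, genome, rng)
    return SimulatedBundle(
        config=config,
        genome=genome,
        sequences=sequences,
        annotations=annotations,
        active_genes=active,
        true_peaks=true_peaks,
        peak_strengths=strengths,
        chip_tracks=chip,
        input_tracks=inputs,
        dropped=dropped,
        expression=expression,
        bound_genes=bound_genes,
        de_table=de_table,
        tf_sets=tf_sets,
        tf_truth_overlap=truth_rates,
        hot_regions=hot,
        planted_motifs=planted_motifs,
    )


def subunit_replicate_peaks(
    bundle: SimulatedBundle, complex_name: str, subunit: str
) -> tuple[list[Interval], list[list[Interval]]]:
    """Truth-derived per-subunit peak intervals: the combined set plus one list
    per replicate with dropped peaks removed (for majority-filter tests)."""
    peaks = bundle.true_peaks[complex_name]
    combined = [p.interval for p in peaks]
    reps = []
    for r in range(bundle.config.n_replicates):
        reps.append(
            [
                p.interval
                for i, p in enumerate(peaks)
                if (subunit, r, i) not in bundle.dropped[complex_name]
            ]
        )
    return combined, reps


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> dict[str, str]:
    """Emit the whole bundle as plain-text standard formats plus truth files.

    Returns a name -> path map of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str, rel: str) -> Path:
        paths[name] = str(outdir / rel)
        return outdir / rel

    write_fasta(bundle.sequences, _p("fasta", "genome.fa"))
    bundle.genome.write_chromsizes(_p("chromsizes", "genome.chrom.sizes"))
    write_gff(bundle.annotations, _p("annotations", "annotations.gff3"))
    for complex_name, subunits in bundle.chip_tracks.items():
        for subunit, reps in subunits.items():
            for r, track in enumerate(reps):
                write_track(
                    track, _p(f"chip/{complex_name}/{subunit}/rep{r + 1}",
                              f"{complex_name}.{subunit}.rep{r + 1}.bedgraph")
                )
        write_track(bundle.input_tracks[complex_name],
                    _p(f"input/{complex_name}", f"{complex_name}.input.bedgraph"))
    for complex_name, ps in bundle.true_peaks.items():
        write_peaks(ps, _p(f"truth/{complex_name}", f"truth.{complex_name}.peaks.bed"))
    bundle.expression.to_csv(_p("expression", "expression.tsv"), sep="\t", index=False)
    bundle.de_table.to_csv(_p("de", "de_results.tsv"), sep="\t", index=False)
    for name, sites in bundle.tf_sets.items():
        from peakscape.core import write_intervals

        write_intervals(sites, _p(f"tf/{name}", f"tf.{name}.bed"))
    from peakscape.core import write_intervals

    write_intervals(bundle.hot_regions, _p("hot", "hot_regions.bed"))
    write_intervals(bundle.planted_motifs, _p("motifs", "truth.motifs.bed"))
    truth = {
        "config": asdict(bundle.config),
        "active_genes": sorted(bundle.active_genes),
        "bound_genes": sorted(bundle.bound_genes),
        "tf_truth_overlap": bundle.tf_truth_overlap,
        "dropped": {c: sorted([list(map(str, t)) for t in v]) for c, v in bundle.dropped.items()},
    }
    with open(_p("truth_json", "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
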