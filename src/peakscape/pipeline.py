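"""End-to-end pipeline on a simulated bundle, with a reproducibility manifest.

Stage order: simulate -> signal -> peaks -> enrich -> profiles -> expression
-> motifs -> features.  Every stage writes into its own subdirectory of the
run directory; the manifest records the config, seed, per-stage timings and a
sha256 digest of every output file, so a rerun under the same seed can be
checked for byte identity.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from peakscape import __version__
from peakscape.core import (
    GENE,
    NCRNA_LONG,
    NCRNA_SHORT,
    TRNA,
    AnalysisConfig,
    CoverageTrack,
    PeakSet,
    derive_promoters,
    derive_3prime,
    flank_both,
    write_peaks,
    write_track,
)
from peakscape import consensus as pc
from peakscape import enrichment as pe
from peakscape import expression as px
from peakscape import features as pf
from peakscape import motifs as pm
from peakscape import profiles as pp
from peakscape import signal as ps
from peakscape.simulate import (
    COMPLEXES,
    SimulatedBundle,
    SimulationConfig,
    simulate,
    subunit_replicate_peaks,
    write_bundle,
)

STAGES = (
    "simulate",
    "signal",
    "peaks",
    "enrich",
    "profiles",
    "expression",
    "motifs",
    "features",
)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Holds in-memory state passed between stages of one run."""

    def __init__(
        self,
        outdir: str | Path,
        sim_config: SimulationConfig | None = None,
        analysis_config: AnalysisConfig | None = None,
        seed: int = 0,
    ):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.sim_config = sim_config or SimulationConfig()
        self.analysis_config = analysis_config or AnalysisConfig()
        self.seed = seed
        self.bundle: SimulatedBundle | None = None
        self.enrichment_tracks: dict[str, CoverageTrack] = {}
        self.final_peaks: dict[str, PeakSet] = {}
        self.timings: dict[str, float] = {}
        self.outputs: list[Path] = []

    # -- helpers ---------------------------------------------------------

    def _dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _record(self, *paths: Path) -> None:
        self.outputs.extend(paths)

    def _save_tsv(self, df: pd.DataFrame, path: Path) -> Path:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        self._record(path)
        return path

    # -- stages ----------------------------------------------------------

    def stage_simulate(self) -> None:
        self.bundle = simulate(self.sim_config, seed=self.seed)
        paths = write_bundle(self.bundle, self._dir("simulate"))
        self._record(*(Path(p) for p in paths.values()))

    def stage_signal(self) -> None:
        b = self._require_bundle()
        outdir = self._dir("signal")
        for complex_name in COMPLEXES:
            input_norm = ps.median_normalize(b.input_tracks[complex_name], b.genome)
            subunit_tracks = []
            for subunit, reps in sorted(b.chip_tracks[complex_name].items()):
                enriched = [
                    ps.subtract_input(ps.median_normalize(t, b.genome), input_norm)
                    for t in reps
                ]
                subunit_tracks.append(ps.merge_replicates(enriched))
            merged = ps.merge_replicates(subunit_tracks)
            self.enrichment_tracks[complex_name] = merged
            path = outdir / f"{complex_name}.enrichment.bedgraph"
            write_track(merged, path)
            with open(outdir / f"{complex_name}.provenance.json", "w") as fh:
                json.dump(merged.provenance, fh, indent=1, sort_keys=True)
            self._record(path, outdir / f"{complex_name}.provenance.json")

    def stage_peaks(self) -> None:
        b = self._require_bundle()
        outdir = self._dir("peaks")
        cfg = self.analysis_config
        for complex_name in COMPLEXES:
            filtered_sets = []
            for subunit in sorted(b.chip_tracks[complex_name]):
                combined, reps = subunit_replicate_peaks(b, complex_name, subunit)
                filtered_sets.append(pc.majority_replicate_filter(combined, reps))
            intervals = pc.consensus_k_of_n(filtered_sets, k=cfg.consensus_k)
            track = self.enrichment_tracks[complex_name]
            with_summits = pc.call_summits(intervals, track)
            min_height = pc.summit_score_median(with_summits)
            final = pc.split_peaks(
                with_summits, track, min_height, separation_float=cfg.separation_float
            )
            self.final_peaks[complex_name] = final
            path = outdir / f"{complex_name}.consensus_peaks.bed"
            write_peaks(final, path)
            self._record(path)

    def stage_enrich(self) -> None:
        b = self._require_bundle()
        outdir = self._dir("enrich")
        cfg = self.analysis_config
        genes = b.annotations.of_class(GENE)
        annotations = {
            "promoter_1kb": derive_promoters(genes, cfg.promoter_len, b.genome),
            "gene_body": [r.interval for r in genes],
            "three_prime_1kb": derive_3prime(genes, cfg.promoter_len, b.genome),
            "tRNA": [r.interval for r in b.annotations.of_class(TRNA)],
            "ncRNA": flank_both(
                b.annotations.of_class(NCRNA_SHORT, NCRNA_LONG), cfg.promoter_len, b.genome
            ),
        }
        rows = []
        for complex_name, peakset in self.final_peaks.items():
            windows = pe.summit_windows(peakset, b.genome, halfwidth=cfg.summit_window)
            rng = np.random.default_rng(self.seed + 1)
            for ann_name, ivs in annotations.items():
                if not ivs:
                    continue
                res = pe.permutation_test(windows, ivs, b.genome, cfg, rng=rng)
                rows.append(
                    {
                        "complex": complex_name,
                        "annotation": ann_name,
                        "observed_fraction": res.observed_fraction,
                        "null_mean_fraction": res.null_mean,
                        "fold_enrichment": res.fold_enrichment,
                        "p_value": res.p_value,
                        "direction": res.direction,
                        "n_peaks": res.n_peaks,
                        "n_permutations": res.n_permutations,
                    }
                )
            tf_table = pe.tf_overlap_table(
                windows, b.tf_sets, b.genome, cfg, hot_regions=b.hot_regions,
                rng=np.random.default_rng(self.seed + 2),
            )
            self._save_tsv(tf_table, outdir / f"{complex_name}.tf_overlap.tsv")
        self._save_tsv(pd.DataFrame(rows), outdir / "annotation_enrichment.tsv")

    def stage_profiles(self) -> None:
        b = self._require_bundle()
        outdir = self._dir("profiles")
        cfg = self.analysis_config
        genes = b.annotations.of_class(GENE)
        expr = dict(zip(b.expression["gene"], b.expression["median"]))
        for complex_name, track in self.enrichment_tracks.items():
            curve = pp.tss_profile(
                track, genes, expr, flank=cfg.heatmap_flank, bin_size=cfg.heatmap_bin
            )
            self._save_tsv(curve, outdir / f"{complex_name}.tss_profile.tsv")
            peakset = self.final_peaks[complex_name]
            anchors = [(p.chrom, p.summit, "+") for p in peakset]
            mat = pp.anchored_matrix(track, anchors, cfg.heatmap_flank, cfg.heatmap_bin)
            mat = pp.order_by_summit_score(mat, peakset)
            mat.write_tsv(outdir / f"{complex_name}.summit_heatmap.tsv")
            self._record(outdir / f"{complex_name}.summit_heatmap.tsv")
            gc = pp.gc_summit_profile(
                b.sequences,
                b.genome,
                [(p.chrom, p.summit) for p in peakset],
                flank=cfg.heatmap_flank,
                bin_size=cfg.heatmap_bin,
                gc_window=cfg.gc_window,
                rng=np.random.default_rng(self.seed + 3),
            )
            self._save_tsv(gc, outdir / f"{complex_name}.gc_summit_profile.tsv")

    def stage_expression(self) -> None:
        b = self._require_bundle()
        outdir = self._dir("expression")
        cfg = self.analysis_config
        genes = b.annotations.of_class(GENE)
        expr = dict(zip(b.expression["gene"], b.expression["median"]))
        rows = []
        for complex_name, track in self.enrichment_tracks.items():
            signal = px.promoter_signal(track, genes, b.genome, upstream=cfg.promoter_signal_len)
            rho_all = px.binding_expression_correlation(signal, expr)
            rho_x = px.binding_expression_correlation(
                signal, expr, genes=genes, scope="X", x_chrom=b.genome.x_chrom
            )
            bound = px.classify_bound_genes(
                genes, self.final_peaks[complex_name], b.genome,
                window=cfg.promoter_len, summit_halfwidth=cfg.summit_window,
            )
            table = px.de_binding_table(b.de_table, bound)
            self._save_tsv(table, outdir / f"{complex_name}.de_binding.tsv")
            rows.append(
                {
                    "complex": complex_name,
                    "spearman_genome": rho_all,
                    "spearman_X": rho_x,
                    "n_bound_genes": int(sum(bound.values())),
                }
            )
        self._save_tsv(pd.DataFrame(rows), outdir / "binding_expression.tsv")

    def stage_motifs(self) -> None:
        b = self._require_bundle()
        outdir = self._dir("motifs")
        pwm = pm.PositionWeightMatrix.from_consensus(b.config.motif_consensus)
        threshold = pwm.default_threshold(0.8)
        hits = pm.scan_genome(pwm, b.sequences, threshold)
        from peakscape.core import write_intervals

        write_intervals(hits, outdir / "motif_hits.bed")
        self._record(outdir / "motif_hits.bed")
        rows = []
        for complex_name, peakset in self.final_peaks.items():
            ivs = peakset.intervals
            bound_frac = pm.motif_bound_fraction(hits, ivs) if hits else float("nan")
            clust = (
                pm.clustering_effect(hits, ivs, b.genome, window=1000)
                if hits
                else {"fold": float("nan")}
            )
            # chromatin context: 2 kb tiles in the top decile of enrichment
            tiles = pf.genome_windows(b.genome, 2000)
            track = self.enrichment_tracks[complex_name]
            med = np.array([np.median(track.data[t.chrom][t.start : t.end]) for t in tiles])
            marked = [t for t, m in zip(tiles, med) if m >= np.quantile(med, 0.9)]
            ctx = pm.context_conditioned_fraction(hits, ivs, marked) if hits else {}
            rows.append(
                {
                    "complex": complex_name,
                    "n_motif_hits": len(hits),
                    "bound_fraction": bound_frac,
                    "clustering_fold": clust.get("fold"),
                    "context_fraction": ctx.get("conditioned_fraction"),
                }
            )
        self._save_tsv(pd.DataFrame(rows), outdir / "motif_stats.tsv")

    def stage_features(self) -> None:
        b = self._require_bundle()
        outdir = self._dir("features")
        cfg = self.analysis_config
        # subunit-level tracks for the correlation heat map
        subunit_tracks: dict[str, CoverageTrack] = {}
        for complex_name in COMPLEXES:
            input_norm = ps.median_normalize(b.input_tracks[complex_name], b.genome)
            for subunit, reps in sorted(b.chip_tracks[complex_name].items()):
                enriched = [
                    ps.subtract_input(ps.median_normalize(t, b.genome), input_norm)
                    for t in reps
                ]
                subunit_tracks[subunit] = ps.merge_replicates(enriched)
        matrix = pf.window_feature_matrix(subunit_tracks, b.genome, window=cfg.corr_window)
        corr, order = pf.correlation_heatmap_order(matrix)
        corr.to_csv(outdir / "subunit_correlation.tsv", sep="\t", float_format="%.6g")
        with open(outdir / "cluster_order.json", "w") as fh:
            json.dump(order, fh)
        self._record(outdir / "subunit_correlation.tsv", outdir / "cluster_order.json")
        for complex_name, peakset in self.final_peaks.items():
            tiles, labels = pf.label_windows(b.genome, peakset, window=cfg.ml_window)
            feats = pf.window_feature_matrix(
                {"enrichment": self.enrichment_tracks[complex_name], **subunit_tracks},
                b.genome,
                window=cfg.ml_window,
            )
            if labels.sum() >= 2 and (~labels).sum() >= 2:
                imp = pf.permutation_importance(
                    feats.reset_index(drop=True), labels, rng_seed=self.seed + 4
                )
                self._save_tsv(imp, outdir / f"{complex_name}.feature_importance.tsv")

    # -- driver ----------------------------------------------------------

    def _require_bundle(self) -> SimulatedBundle:
        if self.bundle is None:
            raise RuntimeError("stage 'simulate' must run before downstream stages")
        return self.bundle

    def run(self, stages: tuple[str, ...] = STAGES) -> dict:
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        for stage in STAGES:  # dependency order is fixed
            if stage not in stages:
                continue
            t0 = time.perf_counter()
            getattr(self, f"stage_{stage}")()
            self.timings[stage] = round(time.perf_counter() - t0, 3)
        manifest = {
            "tool_version": __version__,
            "seed": self.seed,
            "simulation_config": asdict(self.sim_config),
            "analysis_config": asdict(self.analysis_config),
            "timings_s": self.timings,
            "outputs": {
                str(p.relative_to(self.outdir)): sha256_file(p)
                for p in sorted(set(self.outputs))
            },
        }
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest


def run_pipeline(
    outdir: str | Path,
    sim_config: SimulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    seed: int = 0,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Execute the pipeline and return the run manifest."""
    run = PipelineRun(outdir, sim_config, analysis_config, seed=seed)
    return run.run(stages)
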