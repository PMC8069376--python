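"""End-to-end three-arm benchmarks from one config.

Presets
-------
``zymo_even``
    Even mock community: eight bacterial members at 12% each plus two
    eukaryotic members at 2% each, every marker embedded in a host genome
    (genome GC spanning 32.7-66.2%). All three arms are profiled, capture
    bins are assembled and sOTU-called, and the report compares observed
    composition to truth.
``spike_series``
    20 plasmid members at 1e8/1e7/1e6/0 copies each, spiked into a carrier
    background harbouring two endogenous markers. Capture and amplicon
    counts are regressed against the true copy numbers.
``soil_like``
    500 taxa with log-uniform abundances over four orders of magnitude,
    Bacteria-dominant with trace Archaea/Eukarya. Good's coverage versus
    total sequencing effort is compared across arms.

All randomness flows from the config seed; a run is byte-reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capture_sim import (HybridizationModel, LibraryBundle, PcrModel,
                          ReadSimParams, build_libraries)
from .community_sim import (CommunitySample, MarkerFamilySpec, SpikePanelSpec,
                            embed_marker_in_genome, generate_marker_family,
                            make_even_community, make_spike_series)
from .diversity_quant import (alpha_diversity, beta_diversity, coverage_curve,
                              RarefactionParams, recovery_stats)
from .marker_db import ClusterCountTable, CpnType, Domain, MarkerDB, MarkerRecord
from .otu_assembly import AssemblyParams, SotuParams, assemble_cluster, call_asvs, trim_to_sotu
from .probe_design import ProbeDesignParams, design_array
from .profiler import DownsampleParams, ProfileResult, build_index, downsample, profile_sample

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "run_benchmark", "write_report"]

PRESETS = ("zymo_even", "spike_series", "soil_like")


@dataclass(frozen=True)
class BenchmarkConfig:
    preset: str = "zymo_even"
    seed: int = 0
    n_read_pairs: int = 50_000          # per arm
    n_fragments: int = 200_000
    probe_params: ProbeDesignParams = field(default_factory=ProbeDesignParams)
    hyb_model: HybridizationModel = field(default_factory=HybridizationModel)
    pcr_model: PcrModel = field(default_factory=PcrModel)
    read_length: int = 250
    substitution_error_rate: float = 0.005
    assembly: bool = True
    allocation: str | None = None   # default: uniform for spike_series

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")


# ------------------------------------------------------------- communities

def zymo_community(seed: int) -> tuple[MarkerDB, CommunitySample]:
    """Eight bacteria (12% each) + two eukaryotes (2% each), with genomes."""
    spec = MarkerFamilySpec(
        n_taxa=10, seed=seed, target_identity_range=(0.70, 0.85), id_prefix="zymo"
    )
    db = generate_marker_family(spec)
    # last two members are the eukaryotes (type II cytosolic chaperonin)
    records = []
    for i, rec in enumerate(db):
        if i >= 8:
            rec = MarkerRecord(rec.id, rec.taxon, Domain.EUKARYA, CpnType.II,
                               rec.seq, rec.ut_interval)
        records.append(rec)
    db = MarkerDB(records)
    # genome GC grid bracketing the observed extremes (32.7% .. 66.2%)
    gcs = np.concatenate([np.linspace(0.327, 0.662, 8), [0.40, 0.48]])
    genomes = {}
    for i, rec in enumerate(db):
        genomes[rec.id] = embed_marker_in_genome(
            rec, genome_length=40_000, gc=float(gcs[i]), seed=seed + 101 + i
        )
    sample = make_even_community(db, 0.12, 0.02, sample_id="zymo_even", genomes=genomes)
    return db, sample


def spike_community(
    seed: int, spec: SpikePanelSpec | None = None
) -> tuple[MarkerDB, list[CommunitySample]]:
    """20-plasmid spike series in a carrier with two endogenous markers."""
    spec = spec or SpikePanelSpec()
    fam = MarkerFamilySpec(
        n_taxa=spec.n_members + 2, seed=seed, flank_length=0,
        target_identity_range=(0.72, 0.88), id_prefix="panel",
    )
    db = generate_marker_family(fam)
    endo_ids = db.ids[spec.n_members :]
    backgrounds = []
    n_bg = 5
    for g in range(n_bg):
        if g < len(endo_ids):
            genome = embed_marker_in_genome(
                db[endo_ids[g]], genome_length=50_000, gc=0.45,
                seed=seed + 201 + g, genome_id=f"carrier{g}",
            )
        else:
            from .community_sim import _random_seq
            from ._seq import to_str
            rng = np.random.default_rng(seed + 201 + g)
            from .community_sim import GenomeRecord
            genome = GenomeRecord(id=f"carrier{g}", seq=to_str(_random_seq(rng, 50_000, 0.45)))
        backgrounds.append((genome, spec.background_weight / n_bg))
    samples = make_spike_series(db, spec, backgrounds)
    return db, samples


def soil_community(seed: int, n_taxa: int = 500) -> tuple[MarkerDB, CommunitySample]:
    """Soil-like long-tail community: log-uniform abundances over 4 orders."""
    rng = np.random.default_rng(seed)
    fam = MarkerFamilySpec(
        n_taxa=n_taxa, seed=seed, target_identity_range=(0.70, 0.95), id_prefix="soil"
    )
    db = generate_marker_family(fam)
    records = []
    for i, rec in enumerate(db):
        if i >= n_taxa - 5:      # trace Eukarya
            rec = MarkerRecord(rec.id, rec.taxon, Domain.EUKARYA, CpnType.II,
                               rec.seq, rec.ut_interval)
        elif i >= n_taxa - 10:   # trace Archaea
            rec = MarkerRecord(rec.id, rec.taxon, Domain.ARCHAEA, CpnType.II,
                               rec.seq, rec.ut_interval)
        records.append(rec)
    db = MarkerDB(records)
    copies = 10 ** rng.uniform(2.0, 6.0, size=n_taxa)
    genomes = {}
    for i, rec in enumerate(db):
        genomes[rec.id] = embed_marker_in_genome(
            rec, genome_length=40_000, gc=float(rng.uniform(0.35, 0.68)),
            seed=seed + 301 + i,
        )
    sample = CommunitySample(
        sample_id="soil_like",
        members=[(rec.id, float(copies[i])) for i, rec in enumerate(db)],
        abundance_mode="copies",
        genomes=genomes,
    )
    return db, sample


# ------------------------------------------------------------------ runner

def _profile_arms(bundle: LibraryBundle, index) -> dict[str, ProfileResult]:
    return {arm: profile_sample(reads, index) for arm, reads in bundle.arms.items()}


def run_benchmark(config: BenchmarkConfig) -> dict:
    """Run a preset end-to-end; returns the report bundle (dict of tables)."""
    t0 = time.monotonic()
    read_params = ReadSimParams(
        read_length=config.read_length,
        substitution_error_rate=config.substitution_error_rate,
        n_read_pairs=config.n_read_pairs,
    )
    stage = "community_sim"
    try:
        bundle_out: dict = {"preset": config.preset, "seed": config.seed}
        if config.preset == "zymo_even":
            db, sample = zymo_community(config.seed)
            samples = [sample]
        elif config.preset == "spike_series":
            db, samples = spike_community(config.seed)
        else:
            db, sample = soil_community(config.seed)
            samples = [sample]

        stage = "probe_design"
        probes = design_array(db, config.probe_params)
        bundle_out["probe_stats"] = dict(probes.stats)

        stage = "capture_sim"
        allocation = config.allocation or (
            "uniform" if config.preset == "spike_series" else "proportional"
        )
        libraries: dict[str, LibraryBundle] = {}
        for i, s in enumerate(samples):
            libraries[s.sample_id] = build_libraries(
                s, db, probes,
                hyb_model=config.hyb_model, pcr_model=config.pcr_model,
                read_params=read_params, n_fragments=config.n_fragments,
                seed=config.seed * 1000 + i, allocation=allocation,
            )

        stage = "profiler"
        index = build_index(db)
        profiles = {sid: _profile_arms(lib, index) for sid, lib in libraries.items()}

        marker_fractions = pd.DataFrame(
            {
                sid: {arm: lib.arms[arm].marker_fraction() for arm in lib.arms}
                for sid, lib in libraries.items()
            }
        )
        enrichment = pd.Series(
            {sid: lib.enrichment.log10_fold_enrichment for sid, lib in libraries.items()},
            name="log10_fold_enrichment",
        )
        bundle_out["marker_fractions"] = marker_fractions
        bundle_out["enrichment"] = enrichment
        bundle_out["manifests"] = {sid: lib.manifest for sid, lib in libraries.items()}
        bundle_out["truth"] = pd.DataFrame(
            {sid: lib.truth for sid, lib in libraries.items()}
        ).fillna(0.0)

        counts = {}
        for sid, arms in profiles.items():
            for arm, res in arms.items():
                counts[f"{sid}:{arm}"] = res.column
        bundle_out["counts"] = ClusterCountTable(pd.DataFrame(counts))
        bundle_out["mapped_fraction"] = pd.Series(
            {key: profiles[key.split(":")[0]][key.split(":")[1]].mapped_fraction
             for key in counts}
        )

        stage = "analysis"
        if config.preset == "zymo_even":
            _analyse_zymo(bundle_out, config, db, libraries, profiles, index)
        elif config.preset == "spike_series":
            _analyse_spike(bundle_out, config, samples, profiles)
        else:
            _analyse_soil(bundle_out, config, libraries, profiles)
    except Exception as exc:
        raise RuntimeError(f"benchmark stage {stage!r} failed: {exc}") from exc

    bundle_out["elapsed_s"] = round(time.monotonic() - t0, 2)
    return bundle_out


def _analyse_zymo(bundle, config, db, libraries, profiles, index) -> None:
    lib = libraries["zymo_even"]
    arms = profiles["zymo_even"]
    bacterial = [r.id for r in db if r.domain is Domain.BACTERIA]
    comp = {}
    for arm, res in arms.items():
        col = res.column
        bact = col.loc[bacterial]
        comp[arm] = bact / bact.sum() if bact.sum() else bact.astype(float)
    comp_df = pd.DataFrame(comp)
    bundle["bacterial_composition"] = comp_df
    bundle["mean_bacterial_proportion"] = comp_df.mean(axis=0)

    # inter-technique down-sampling to the smallest mapped library
    depth = min(res.n_mapped for res in arms.values())
    ds = {arm: downsample(res.column, DownsampleParams(depth=depth, seed=config.seed))
          for arm, res in arms.items()}
    bundle["downsampled_counts"] = pd.DataFrame(ds)
    bundle["downsample_depth"] = depth
    bundle["beta"] = beta_diversity(pd.DataFrame(ds))

    if config.assembly:
        rows = []
        asv_rows = []
        cap = lib.capture
        res = arms["capture"]
        for ri, rid in enumerate(index.record_ids):
            rec = db[rid]
            mask = res.assignments == ri
            if mask.sum() < 5:
                continue
            sub = _subset_reads(cap, np.flatnonzero(mask))
            contigs = assemble_cluster(sub, AssemblyParams(), cluster_id=rid, truth=rec)
            if contigs:
                best = contigs[0]
                rows.append({"cluster_id": rid, "detected": "+",
                             "assembly_length": best.length,
                             "identity": round(best.identity_to_truth, 4)})
            else:
                rows.append({"cluster_id": rid, "detected": "-",
                             "assembly_length": 0, "identity": np.nan})
            trimmed = trim_to_sotu(sub, rec, SotuParams())
            asvs = call_asvs(trimmed, SotuParams(), cluster_id=rid)
            asv_rows.append({"cluster_id": rid,
                             "sotu_detected": "+" if asvs else "NF",
                             "n_asvs": len(asvs)})
        bundle["assembly_report"] = pd.DataFrame(rows).set_index("cluster_id")
        bundle["asv_report"] = pd.DataFrame(asv_rows).set_index("cluster_id")


def _analyse_spike(bundle, config, samples, profiles) -> None:
    member_ids = [rid for rid, _ in samples[0].members]
    truth = pd.DataFrame(
        {s.sample_id: {rid: ab for rid, ab in s.members} for s in samples}
    ).loc[member_ids]
    bundle["spike_truth"] = truth
    recovery = {}
    for arm in ("capture", "amplicon"):
        cols = {}
        mapped = [profiles[s.sample_id][arm].n_mapped for s in samples]
        depth = min(m for m in mapped if m > 0)
        for s in samples:
            col = profiles[s.sample_id][arm].column
            if col.sum() >= depth:
                col = downsample(col, DownsampleParams(depth=depth, seed=config.seed))
            cols[s.sample_id] = col.loc[member_ids]
        counts = pd.DataFrame(cols)
        stats = recovery_stats(truth, counts)
        recovery[arm] = stats
        bundle[f"spike_counts_{arm}"] = counts
    bundle["recovery"] = pd.DataFrame(
        {arm: st.per_member_r2 for arm, st in recovery.items()}
    )
    bundle["pooled_spearman"] = pd.Series(
        {arm: st.pooled_spearman for arm, st in recovery.items()}
    )


def _analyse_soil(bundle, config, libraries, profiles) -> None:
    lib = libraries["soil_like"]
    arms = profiles["soil_like"]
    cols = {arm: res.column for arm, res in arms.items()}
    fractions = {arm: max(lib.arms[arm].marker_fraction(), 1e-6) for arm in cols}
    # each arm is rarefied over the part of the 250..2750 grid its own
    # mapped total supports; effort rescaling makes the arms comparable
    curves = []
    alpha = {}
    for arm, col in cols.items():
        total = int(col.sum())
        depths = tuple(d for d in range(250, 2751, 250) if d <= total)
        if not depths:
            logger.warning("arm %s: only %d mapped pairs, below the rarefaction "
                           "grid; skipped", arm, total)
            continue
        params = RarefactionParams(depths=depths, reps=25, seed=config.seed)
        curves.append(coverage_curve({arm: col}, {arm: fractions[arm]}, params))
        alpha[arm] = alpha_diversity(col, params).table
    bundle["coverage_curve"] = pd.concat(curves, ignore_index=True)
    bundle["alpha"] = alpha


def _subset_reads(reads, idx: np.ndarray):
    from .capture_sim import PairedReads

    return PairedReads(
        r1=reads.r1[idx], r2=reads.r2[idx], l1=reads.l1[idx], l2=reads.l2[idx],
        source_ids=reads.source_ids, source_index=reads.source_index[idx],
        carries_marker=reads.carries_marker[idx],
    )


# ------------------------------------------------------------------ report

def write_report(bundle: dict, outdir: str | Path) -> Path:
    """Write the report bundle as TSVs plus a markdown summary."""
    if not bundle or "preset" not in bundle:
        raise ValueError("empty or incomplete benchmark bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.6g"

    def dump(name: str, df: pd.DataFrame) -> None:
        df.to_csv(outdir / f"{name}.tsv", sep="\t", float_format=ff)

    lines = [f"# CaptureSeq benchmark report — preset `{bundle['preset']}`",
             "", f"seed: {bundle['seed']}", ""]

    dump("marker_fractions", bundle["marker_fractions"])
    dump("mapped_fraction", bundle["mapped_fraction"].to_frame("mapped_fraction"))
    dump("counts", bundle["counts"].counts)
    dump("truth", bundle["truth"])
    dump("enrichment", bundle["enrichment"].to_frame())

    mf = bundle["marker_fractions"]
    lines.append("## Marker read fractions per arm\n")
    lines.append(mf.to_string(float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    for sid, val in bundle["enrichment"].items():
        if np.isfinite(val):
            lines.append(f"- capture enrichment, sample `{sid}`: log10 fold = {val:.2f}")
        else:
            lines.append(f"- capture enrichment, sample `{sid}`: unbounded "
                         "(no off-target fragment captured at this pool size)")
    lines.append("")

    if "mean_bacterial_proportion" in bundle:
        dump("bacterial_composition", bundle["bacterial_composition"])
        dump("downsampled_counts", bundle["downsampled_counts"])
        lines.append("## Even-community composition (bacterial clusters)\n")
        for arm, v in bundle["mean_bacterial_proportion"].items():
            lines.append(f"- mean bacterial proportion, {arm} arm: {v * 100:.1f}%")
        lines.append("")
        if "assembly_report" in bundle:
            dump("assembly_report", bundle["assembly_report"])
            dump("asv_report", bundle["asv_report"])
            lines.append("## Capture-arm assembly\n")
            lines.append(bundle["assembly_report"].to_string())
            lines.append("")
    if "recovery" in bundle:
        dump("recovery_r2", bundle["recovery"])
        dump("spike_truth", bundle["spike_truth"])
        for arm in ("capture", "amplicon"):
            dump(f"spike_counts_{arm}", bundle[f"spike_counts_{arm}"])
        lines.append("## Spike-in recovery (Pearson r² vs true copies)\n")
        lines.append(bundle["recovery"].to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append(f"pooled Spearman ρ: "
                     + ", ".join(f"{a}={v:.3f}" for a, v in bundle["pooled_spearman"].items()))
        lines.append("")
    if "coverage_curve" in bundle:
        dump("coverage_curve", bundle["coverage_curve"])
        for arm, tab in bundle["alpha"].items():
            dump(f"alpha_{arm}", tab)
        lines.append("## Good's coverage vs total effort\n")
        cc = bundle["coverage_curve"]
        for arm in cc["method"].unique():
            sub = cc[cc["method"] == arm]
            lines.append(
                f"- {arm}: coverage {sub['goods_coverage'].iloc[-1]:.4f} at effort "
                f"{sub['effort'].iloc[-1]:.0f}"
            )
        lines.append("")

    manifest = {
        "preset": bundle["preset"],
        "seed": bundle["seed"],
        "capturesim_version": __version__,
        "samples": bundle["manifests"],
        "probe_stats": bundle["probe_stats"],
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    (outdir / "report.md").write_text("\n".join(lines))
    return outdir
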