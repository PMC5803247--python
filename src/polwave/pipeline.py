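"""Stage orchestration: simulate -> filter -> metrics -> diff -> waves -> rates.

Every stage reads the data directory layout produced by
``simulate.write_fixture_set`` (bedGraph pairs + sample sheet + BED6 genes
+ chrom.sizes) -- real data prepared in the same shape works identically
-- writes its tables under the output directory, and appends a manifest
entry (parameters, input file hashes, seed, per-gene skip tallies) so
every shrinking gene count is auditable.  Re-running a stage on identical
inputs and seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, differential, hmm, metrics, rates, simulate
from .tracks import SignalTrack, combine_tracks, read_bedgraph_pair, read_genes, write_genes_bed6

STAGES = ("simulate", "filter", "metrics", "diff", "waves", "rates")

# printed defaults of the analysis: region bounds, thresholds, window sizes,
# per-timepoint init distances (minutes -> bp)
DEFAULT_PARAMS = {
    "window_bp": 50,
    "upstream_bp": 500,
    "p_threshold": 0.01,
    "diff_threshold": 0.01,
    "tss_search_bp": 250,
    "tss_min_excess": 4.0,
    "bin_bp": 10,
    "span": [-250, 4000],
    "advancing_init_bp": {0.5: 1000, 1.0: 1500, 2.5: 2500, 5.0: 3500},
    "clearing_init_bp": {0.5: 3000, 1.0: 4000, 2.5: 5500},
    "suggest_inits": True,
    "tsmooth": 5.0,
    "clearing_state1_bp": 1000,
    "advancing_min_length": 4000,
    "clearing_min_length": 6000,
    "clearing_max_timepoint": 2.5,
    "metrics_timepoint": 5.0,
    "bootstrap_fraction": 0.10,
    "bootstrap_reps": 1000,
    "termination_window_bp": 1000,
    "termination_fraction": 0.25,
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    data_dir: str
    out_dir: str
    seed: int = 1
    params: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(out_dir: Path, stage: str, config: RunConfig, inputs: list[Path],
                    info: dict) -> None:
    entry = {
        "stage": stage,
        "seed": config.seed,
        "params": {k: v for k, v in sorted(config.params.items())},
        "inputs": {p.name: _hash_file(p) for p in sorted(inputs) if p.exists()},
        **info,
    }
    path = out_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = json.loads(json.dumps(entry, default=str))
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


class PipelineData:
    """Lazy-loaded data directory: tracks, genes, sample sheet."""

    def __init__(self, data_dir):
        self.dir = Path(data_dir)
        self.sheet = pd.read_csv(self.dir / "sample_sheet.tsv", sep="\t")
        self.chrom_sizes = {}
        with open(self.dir / "chrom.sizes") as fh:
            for line in fh:
                chrom, size = line.split()
                self.chrom_sizes[chrom] = int(size)
        self.genes = read_genes(self.dir / "genes.bed")
        self._tracks: dict[str, SignalTrack] = {}

    def track(self, sample_id: str) -> SignalTrack:
        if sample_id not in self._tracks:
            row = self.sheet.set_index("sample_id").loc[sample_id]
            tp = row["timepoint"]
            self._tracks[sample_id] = read_bedgraph_pair(
                self.dir / row["plus_bedgraph"],
                self.dir / row["minus_bedgraph"],
                self.chrom_sizes,
                spike_mapped_reads=float(row["spike_reads"]),
                sample_id=sample_id,
                timepoint=float(tp) if pd.notna(tp) and tp != "" else None,
                treatment=str(row["treatment"]),
            )
        return self._tracks[sample_id]

    def combined(self, treatment: str, timepoint: float | None = None) -> SignalTrack:
        sel = self.sheet[self.sheet["treatment"] == treatment]
        if timepoint is not None:
            sel = sel[pd.to_numeric(sel["timepoint"]) == timepoint]
        if sel.empty:
            raise ValueError(f"no samples with treatment={treatment!r} timepoint={timepoint}")
        return combine_tracks([self.track(s) for s in sel["sample_id"]])

    def treated_timepoints(self) -> list[float]:
        sel = self.sheet[self.sheet["treatment"] == "treated"]
        return sorted(pd.to_numeric(sel["timepoint"]).unique())


def run(stage: str, config: RunConfig) -> dict:
    """Run one stage (or 'all') and return the artifacts it produced."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        art = {}
        for s in STAGES:
            art[s] = run(s, config)
        return art
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    return _STAGE_FUNCS[stage](config, out_dir)


def _stage_simulate(config: RunConfig, out_dir: Path) -> dict:
    sim_cfg = simulate.SimulationConfig(**{"seed": config.seed, **config.sim})
    fixture = simulate.write_fixture_set(sim_cfg, config.data_dir)
    _write_manifest(out_dir, "simulate", config, [], {
        "n_genes": len(fixture["genes"]),
        "data_dir": str(config.data_dir),
    })
    return fixture


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' stage first"
        )
    return path


def _stage_filter(config: RunConfig, out_dir: Path) -> dict:
    data = PipelineData(config.data_dir)
    p = config.params
    untreated = data.combined("untreated")
    procap_ids = data.sheet[data.sheet["treatment"] == "procap"]["sample_id"]
    if procap_ids.empty:
        raise ValueError("no PRO-cap sample in the sample sheet; cannot observe TSSs")
    procap = data.track(procap_ids.iloc[0])
    kept, report = annotate.filter_genes(
        data.genes, procap, untreated, data.chrom_sizes,
        p_threshold=p["p_threshold"], tss_search=p["tss_search_bp"],
        tss_min_excess=p["tss_min_excess"],
    )
    report.to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
    write_genes_bed6(kept, out_dir / "filtered_genes.bed")
    tallies = {
        "n_input": len(data.genes),
        "n_observed_tss": int(report["has_observed_tss"].sum()),
        "n_active": int(report["active"].sum()),
        "n_readthrough_pass": int(report["readthrough_pass"].sum()),
        "n_final": len(kept),
    }
    _write_manifest(out_dir, "filter", config,
                    [data.dir / "genes.bed", data.dir / "sample_sheet.tsv"], tallies)
    return {"genes": kept, "report": report, **tallies}


def _filtered_genes(config: RunConfig, out_dir: Path):
    path = _require(out_dir / "filtered_genes.bed", "filter")
    return read_genes(path)


def _stage_metrics(config: RunConfig, out_dir: Path) -> dict:
    data = PipelineData(config.data_dir)
    p = config.params
    genes = _filtered_genes(config, out_dir)
    untreated = data.combined("untreated")
    tp = p["metrics_timepoint"]
    treated = data.combined("treated", tp)

    pi_u = metrics.pausing_table(untreated, genes)
    pi_t = metrics.pausing_table(treated, genes)
    pi_u["quartile"] = metrics.pi_quartiles(pi_u)
    pi_u.to_csv(out_dir / "pausing_untreated.tsv", sep="\t", index=False)
    pi_t.to_csv(out_dir / "pausing_treated.tsv", sep="\t", index=False)
    cdf = metrics.pi_cdf_compare(pi_t, pi_u)
    pd.DataFrame({
        "log10_pi": cdf["grid"],
        "cdf_treated": cdf["cdf_treated"],
        "cdf_untreated": cdf["cdf_untreated"],
    }).to_csv(out_dir / "pi_cdf.tsv", sep="\t", index=False)

    lo, hi = p["span"]
    rows = []
    for t in [None] + data.treated_timepoints():
        track = untreated if t is None else data.combined("treated", t)
        comp = metrics.composite_profile(track, genes, "tss", (lo, hi), p["bin_bp"])
        rows.append(pd.DataFrame({
            "timepoint": "untreated" if t is None else t,
            "bin_start": comp.bin_centers - p["bin_bp"] / 2,
            "mean_signal": comp.values,
        }))
    pd.concat(rows).to_csv(out_dir / "composite_profiles.tsv", sep="\t", index=False)

    fc = metrics.foldchange_matrix(treated, untreated, genes, (lo, hi), p["bin_bp"])
    fc.to_csv(out_dir / "foldchange_matrix.tsv", sep="\t")

    term = {}
    try:
        for label, track in (("untreated", untreated), ("treated", treated)):
            tm = metrics.termination_zone_metrics(
                track, genes, p["termination_window_bp"], p["termination_fraction"],
                p["bin_bp"],
            )
            term[label] = {k: v for k, v in tm.items() if k != "profile"}
    except ValueError as exc:
        warnings.warn(f"termination-zone metrics skipped: {exc}")
    if term:
        pd.DataFrame(term).to_csv(out_dir / "termination_zone.tsv", sep="\t")

    info = {"ks_statistic": cdf["ks_statistic"], "ks_p": cdf["ks_p"],
            "median_log10_pi_shift": cdf["median_shift"], "n_genes": len(genes)}
    _write_manifest(out_dir, "metrics", config, [out_dir / "filtered_genes.bed"], info)
    return {"pi_untreated": pi_u, "pi_treated": pi_t, "cdf": cdf, "foldchange": fc,
            "termination": term, **info}


def _stage_diff(config: RunConfig, out_dir: Path) -> dict:
    data = PipelineData(config.data_dir)
    p = config.params
    genes = _filtered_genes(config, out_dir)
    tp = p["metrics_timepoint"]
    sel = data.sheet[
        (data.sheet["treatment"] == "untreated")
        | ((data.sheet["treatment"] == "treated") & (pd.to_numeric(data.sheet["timepoint"]) == tp))
    ]
    tracks = {s: data.track(s) for s in sel["sample_id"]}
    counts, size_factors = differential.count_regions(tracks, genes)
    condition = pd.Series({s: tracks[s].treatment for s in tracks})
    res = differential.differential_table(counts, size_factors, condition, genes,
                                          threshold=p["diff_threshold"])
    counts.to_csv(out_dir / "region_counts.tsv", sep="\t")
    res.to_csv(out_dir / "differential.tsv", sep="\t")
    mat = differential.classify_changes(res, genes, threshold=p["diff_threshold"])
    mat.to_csv(out_dir / "change_calls.tsv", sep="\t")
    info = {
        "n_gene_regions": len(res),
        "n_excluded_short": len(counts.attrs.get("excluded", [])),
        "n_up": int((res["call"] == "up").sum()),
        "n_down": int((res["call"] == "down").sum()),
    }
    _write_manifest(out_dir, "diff", config, [out_dir / "filtered_genes.bed"], info)
    return {"counts": counts, "results": res, "calls": mat, **info}


def _wave_calls(
    data: PipelineData, genes, p: dict, variant: str
) -> tuple[dict[str, list[hmm.WaveCall]], pd.DataFrame]:
    untreated = data.combined("untreated")
    if variant == "advancing":
        min_len, upstream = p["advancing_min_length"], p["upstream_bp"]
        inits = {float(k): v for k, v in p["advancing_init_bp"].items()}
        tps = [t for t in data.treated_timepoints() if t > 0]
    else:
        min_len, upstream = p["clearing_min_length"], 0
        inits = {float(k): v for k, v in p["clearing_init_bp"].items()}
        tps = [t for t in data.treated_timepoints()
               if 0 < t <= p["clearing_max_timepoint"]]
    cohort = [g for g in genes if g.length > min_len]
    calls: dict[str, list[hmm.WaveCall]] = {g.gene_id: [] for g in cohort}
    rows = []
    for t in tps:
        treated = data.combined("treated", t)
        wdiffs = [
            hmm.windowed_difference(treated, untreated, g, p["window_bp"], upstream, t)
            for g in cohort
        ]
        if p["suggest_inits"] or float(t) not in inits:
            init = hmm.suggest_init_distance(wdiffs, variant, p["clearing_state1_bp"])
        else:
            init = inits[float(t)]
        for g, wd in zip(cohort, wdiffs):
            if variant == "advancing":
                _, call = hmm.fit_advancing_hmm(wd, init)
            else:
                _, call = hmm.fit_clearing_hmm(wd, init, p["tsmooth"],
                                               p["clearing_state1_bp"])
            calls[g.gene_id].append(call)
            rows.append({
                "gene_id": g.gene_id, "variant": variant, "timepoint": t,
                "distance_bp": call.distance_bp, "kl": call.kl,
                "converged": call.converged, "quality_pass": call.quality_pass,
                "init_distance": call.init_distance,
            })
    return calls, pd.DataFrame(rows)


def _stage_waves(config: RunConfig, out_dir: Path) -> dict:
    data = PipelineData(config.data_dir)
    p = config.params
    genes = _filtered_genes(config, out_dir)
    out = {}
    frames = []
    for variant in ("advancing", "clearing"):
        calls, table = _wave_calls(data, genes, p, variant)
        kept = hmm.filter_wave_series(calls)
        out[variant] = {"calls": calls, "kept": kept}
        table["series_kept"] = table["gene_id"].isin(kept)
        frames.append(table)
    pd.concat(frames).to_csv(out_dir / "wave_calls.tsv", sep="\t", index=False)
    info = {
        "n_advancing_cohort": len(out["advancing"]["calls"]),
        "n_advancing_kept": len(out["advancing"]["kept"]),
        "n_clearing_cohort": len(out["clearing"]["calls"]),
        "n_clearing_kept": len(out["clearing"]["kept"]),
    }
    _write_manifest(out_dir, "waves", config, [out_dir / "filtered_genes.bed"], info)
    return {**out, **info}


def _stage_rates(config: RunConfig, out_dir: Path) -> dict:
    p = config.params
    path = _require(out_dir / "wave_calls.tsv", "waves")
    table = pd.read_csv(path, sep="\t")
    ests = {}
    for variant in ("advancing", "clearing"):
        sub = table[(table["variant"] == variant) & table["series_kept"]]
        calls = {
            gid: [
                hmm.WaveCall(gid, r.timepoint, r.distance_bp, r.kl, r.converged,
                             r.quality_pass, r.init_distance, variant)
                for r in grp.itertuples()
            ]
            for gid, grp in sub.groupby("gene_id")
        }
        if not calls:
            warnings.warn(f"no {variant} wave series survived filtering; rate skipped")
            continue
        est = rates.fit_rate(calls)
        est.bootstrap_slopes = rates.bootstrap_rate(
            calls, p["bootstrap_fraction"], p["bootstrap_reps"], seed=config.seed
        )
        est.bootstrap_seed = config.seed
        ests[variant] = est
    summary = {}
    for variant, est in ests.items():
        lo, hi = est.bootstrap_interval()
        summary[variant] = {
            "slope_bp_per_min": est.slope, "intercept_bp": est.intercept,
            "r_squared": est.r_squared, "n_genes": est.n_genes,
            "n_points": est.n_points, "bootstrap_ci95": [lo, hi],
            "gene_slope_mean": est.gene_slope_mean, "gene_slope_sd": est.gene_slope_sd,
        }
    if len(ests) == 2:
        summary["comparison"] = rates.compare_rates(ests["advancing"], ests["clearing"])
    (out_dir / "rates.json").write_text(json.dumps(summary, indent=2) + "\n")
    pd.DataFrame([
        {"variant": v, "gene_id": g, "slope_bp_per_min": s}
        for v, est in ests.items() for g, s in est.per_gene_slopes.items()
    ]).to_csv(out_dir / "per_gene_rates.tsv", sep="\t", index=False)
    _write_manifest(out_dir, "rates", config, [path], {
        k: v for k, v in summary.items() if k != "comparison"
    })
    return {"estimates": ests, "summary": summary}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "metrics": _stage_metrics,
    "diff": _stage_diff,
    "waves": _stage_waves,
    "rates": _stage_rates,
}
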