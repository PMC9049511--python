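"""Config-driven orchestration of the full analysis chain.

A run is described by a YAML config (schema version 1) and executes, in
dependency order: simulate -> filter -> distances/tree -> sharing ->
significance -> dating -> diversity -> dstat. Every stage writes plain
TSV/JSON/newick files into the run directory and the run report records
seeds, parameters, warnings, and the sha256 checksum of every output, so
a rerun with the same config and seed is verifiably identical.

Stages can be toggled; a disabled stage's downstream consumers fall back
to the artifact already on disk in the run directory and fail with a
clear error naming the missing stage otherwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import GenotypeDataset, HaplotypePanel, call_rate_filter, read_ped_map, \
    read_vcf, write_ped_map, write_vcf
from .simulate import (ChromSpec, DemographyConfig, PopSpec, Pulse,
                       clade_config, make_calibration_panel, simulate,
                       single_population_config, two_population_config)
from .phylo import bootstrap_support, ibs_distance, neighbor_joining, \
    root_with_outgroup
from .sharing import SharingParams, breed_pair_summary, detect_segments, \
    significance_call
from .dating import (CalibrationPoint, breed_ranges, estimate_years,
                     fit_calibration, paper_default_calibration)
from .diversity import (d_statistic, inbreeding_f, ne_from_ld, nucleotide_pi,
                        population_frequencies)

logger = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "filter", "distances", "tree", "sharing",
              "significance", "dating", "diversity", "dstat"]

DEFAULTS = {
    "schema": 1,
    "seed": 0,
    "filter": {"sample_min": 0.9, "marker_min": 0.9},
    "tree": {"bootstraps": 100, "outgroup": None},
    "sharing": {"window": 1000, "overlap": 25, "min_markers": 25,
                "min_cm": 1.0, "percentile": 95.0},
    "dating": {"calibration": "paper-default", "sampling_year": 2019,
               "split_times": [10, 20, 35, 50]},
    "diversity": {"pi_window": 500000},
    "dstat": {"quads": [], "block_bp": 5e6},
}


class StageError(RuntimeError):
    pass


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    merged = json.loads(json.dumps(DEFAULTS))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    if merged.get("schema") != 1:
        raise ValueError("unsupported config schema version")
    return merged


def demography_from_config(block: dict, seed: int) -> DemographyConfig:
    """Build a DemographyConfig from the config's ``simulate`` block."""
    kw = {}
    for key in ("chromosomes", "founder_size", "founder_law", "samples_per_pop",
                "generation_time", "burnin", "clades"):
        if key in block:
            kw[key] = block[key]
    if "chromosomes" in kw:
        kw["chromosomes"] = [ChromSpec(*c) for c in kw["chromosomes"]]
    if "founder_law" in kw:
        kw["founder_law"] = tuple(kw["founder_law"])
    scenario = block.get("scenario", "custom")
    if scenario == "two_pop":
        return two_population_config(block["split_gen"], seed=seed, **kw)
    if scenario == "single":
        return single_population_config(block.get("generations", 0), seed=seed, **kw)
    if scenario == "clade":
        return clade_config(block.get("n_clades", 3),
                            block.get("breeds_per_clade", 3),
                            block.get("within_gen", 15),
                            block.get("across_gen", 150), seed=seed, **kw)
    pops = [PopSpec(**p) for p in block["populations"]]
    pulses = [Pulse(**p) for p in block.get("pulses", [])]
    return DemographyConfig(populations=pops, pulses=pulses, seed=seed, **kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config) -> dict:
    """Execute the configured stages; returns the run report dict."""
    cfg = load_config(config)
    outdir = Path(cfg.get("output_dir", "haplodate_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", ALL_STAGES)
    seed = int(cfg["seed"])
    report = {"tool": "haplodate", "version": __version__, "config": cfg,
              "warnings": [], "headline": {}, "checksums": {}}

    panel: HaplotypePanel | None = None
    ds: GenotypeDataset | None = None
    clade_map: dict = {}

    # --- data acquisition ---------------------------------------------
    if "simulate" in stages and "simulate" in cfg:
        dem = demography_from_config(cfg["simulate"], seed)
        res = simulate(dem)
        panel, ds = res.panel, res.dataset
        clade_map = dem.clades or {}
        write_ped_map(ds, outdir / "sim.ped", outdir / "sim.map",
                      outdir / "sim.samples.tsv")
        write_vcf(panel, outdir / "sim.vcf")
        res.truth.to_json(outdir / "truth.json")
        report["headline"]["n_samples"] = ds.n_samples
        report["headline"]["n_markers"] = ds.markers.n_markers
        report["_sim_config"] = dem
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        if "vcf" in inp:
            panel = read_vcf(inp["vcf"], require_phased=True,
                             sidecar_path=inp.get("sidecar"))
            ds = panel.to_genotypes()
        elif "ped" in inp:
            ds = read_ped_map(inp["ped"], inp["map"], inp.get("sidecar"))
        else:
            raise StageError("inputs must provide 'vcf' or 'ped'+'map'")
        if "clades" in inp:
            clade_map = dict(inp["clades"])
    else:
        raise StageError("no data source: enable the 'simulate' stage with a "
                         "simulate block, or provide 'inputs'")
    if not clade_map and ds is not None:
        clade_map = dict(zip(ds.samples["breed"], ds.samples["clade"]))
        clade_map = {k: v for k, v in clade_map.items() if v is not None}

    # --- filtering -----------------------------------------------------
    if "filter" in stages and ds is not None:
        f = cfg["filter"]
        ds = call_rate_filter(ds, f["sample_min"], f["marker_min"])

    # --- distances & tree ---------------------------------------------
    if "distances" in stages:
        dm = ibs_distance(ds)
        dm.to_tsv(outdir / "distances.tsv")
    if "tree" in stages:
        t = cfg["tree"]
        st = bootstrap_support(ds, n_reps=int(t["bootstraps"]), seed=seed)
        if t.get("outgroup"):
            st = root_with_outgroup(st, t["outgroup"])
        st.write_newick(outdir / "tree.nwk")

    # --- sharing & significance ---------------------------------------
    summaries = None
    if "sharing" in stages:
        if panel is None:
            raise StageError("stage 'sharing' requires phased input "
                             "(simulate stage or a phased VCF)")
        sh = cfg["sharing"]
        params = SharingParams(int(sh["window"]), int(sh["overlap"]),
                               int(sh["min_markers"]), float(sh["min_cm"]))
        breeds = sorted(panel.samples["breed"].unique())
        summaries = []
        seg_rows = []
        for i, a in enumerate(breeds):
            for b in breeds[i + 1:]:
                summaries.append(breed_pair_summary(panel, a, b, params))
        pd.DataFrame([{"breedA": s.breed_a, "breedB": s.breed_b,
                       "n_pairs": s.n_pairs, "median_bp": s.median_bp}
                      for s in summaries]).to_csv(
            outdir / "sharing_summary.tsv", sep="\t", index=False)
    elif "significance" in stages or "dating" in stages:
        path = outdir / "sharing_summary.tsv"
        if not path.exists():
            raise StageError("stage 'sharing' is disabled and no "
                             "sharing_summary.tsv is present in the run dir")
        df = pd.read_csv(path, sep="\t")
        from .sharing import PairSharingSummary
        summaries = [PairSharingSummary(r.breedA, r.breedB,
                                        np.array([r.median_bp]), r.median_bp,
                                        int(r.n_pairs))
                     for r in df.itertuples()]

    if "significance" in stages:
        if not clade_map:
            raise StageError("stage 'significance' requires clade labels")
        sig = significance_call(summaries, clade_map,
                                float(cfg["sharing"]["percentile"]))
        report["headline"]["threshold_bp"] = sig.threshold_bp
        report["headline"]["n_flagged"] = int(sum(sig.flagged.values()))
        pd.DataFrame([{"breedA": a, "breedB": b, "flagged": v}
                      for (a, b), v in sorted(sig.flagged.items())]).to_csv(
            outdir / "significance.tsv", sep="\t", index=False)

    # --- dating --------------------------------------------------------
    if "dating" in stages:
        dcfg = cfg["dating"]
        if dcfg["calibration"] == "paper-default":
            model = paper_default_calibration()
        else:
            if "_sim_config" not in report:
                raise StageError("calibration 'fit' requires the simulate stage")
            dem = report["_sim_config"]
            sh = cfg["sharing"]
            params = SharingParams(int(sh["window"]), int(sh["overlap"]),
                                   int(sh["min_markers"]), float(sh["min_cm"]))
            pts = []
            for label, years, cpanel in make_calibration_panel(
                    dem, dcfg["split_times"], seed):
                pa, pb = sorted(cpanel.samples["breed"].unique())
                s = breed_pair_summary(cpanel, pa, pb, params)
                pts.append(CalibrationPoint(label, years, s.median_bp))
            model = fit_calibration(pts, int(dcfg["sampling_year"]))
        model.sampling_year = int(dcfg["sampling_year"])
        model.to_json(outdir / "calibration.json")
        estimates = [estimate_years(model, s.median_bp, s.breed_a, s.breed_b)
                     for s in summaries]
        pd.DataFrame([vars(e) for e in estimates]).to_csv(
            outdir / "dates.tsv", sep="\t", index=False)
        breeds = sorted({b for e in estimates for b in (e.breed_a, e.breed_b)})
        rows = []
        for b in breeds:
            rng_ = breed_ranges(estimates, b, [x for x in breeds if x != b])
            rows.append({"breed": b, "min_year": rng_.min_year,
                         "max_year": rng_.max_year})
        pd.DataFrame(rows).to_csv(outdir / "ranges.tsv", sep="\t", index=False)
        report["headline"]["date_ranges"] = {r["breed"]: [r["min_year"], r["max_year"]]
                                             for r in rows}

    # --- diversity -----------------------------------------------------
    if "diversity" in stages:
        results, breed_f = inbreeding_f(ds)
        pd.DataFrame([vars(r) for r in results]).to_csv(
            outdir / "f.tsv", sep="\t", index=False)
        breed_f.to_csv(outdir / "f_breed.tsv", sep="\t", index=False)
        windows = nucleotide_pi(panel if panel is not None else ds,
                                int(cfg["diversity"]["pi_window"]))
        pd.DataFrame([vars(w) for w in windows]).to_csv(
            outdir / "pi.tsv", sep="\t", index=False)
        nes = ne_from_ld(ds)
        pd.DataFrame([vars(n) for n in nes]).to_csv(
            outdir / "ne.tsv", sep="\t", index=False)

    if "dstat" in stages and cfg["dstat"]["quads"]:
        rows = []
        for quad in cfg["dstat"]["quads"]:
            freqs = [population_frequencies(ds, b) for b in quad]
            r = d_statistic(*freqs, ds.markers.chrom, ds.markers.bp,
                            float(cfg["dstat"]["block_bp"]), labels=tuple(quad))
            rows.append({"quad": "|".join(quad), "abba": r.abba, "baba": r.baba,
                         "d": r.d, "se": r.se, "z": r.z,
                         "n_blocks": r.n_blocks})
        pd.DataFrame(rows).to_csv(outdir / "dstat.tsv", sep="\t", index=False)

    # --- report --------------------------------------------------------
    report.pop("_sim_config", None)
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "report.json":
            report["checksums"][p.name] = _sha256(p)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
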