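"""End-to-end orchestration: qc -> roh -> inbreeding -> landscape -> sweep -> ne -> assoc.

A run is driven by a TOML config with one section per stage; every resolved
parameter (including defaults) is echoed into a JSON run manifest together
with input checksums and per-stage row counts, so a run can be reproduced
bit-identically from the manifest alone.  Unknown config keys are an error.
Stage failures abort with the stage name; partial outputs keep a
``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
import tomllib
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import __version__
from .assoc import linear_assoc
from .core import GenotypeMatrix
from .inbreeding import DEFAULT_L_AUTO_BP, correlate_inbreeding, inbreeding_table
from .io import (
    read_intervals,
    read_ped_map,
    read_phenotypes,
    read_vcf,
    write_intervals,
    write_ped_map,
    write_phenotypes,
    write_vcf,
)
from .landscape import call_coldspots, call_hotspots, flank_regions, occurrence, overlap_intervals
from .popgen import het_stats, ne_ld, windowed_fst, windowed_pi, windowed_tajima_d
from .qc import QCParams, apply_qc
from .roh import ROHParams, detect_roh, resolve_min_snp_count
from .sim import RohPlanItem, SimConfig, simulate_dataset, simulate_phenotypes

log = logging.getLogger("rohscape.pipeline")

KNOWN_SECTIONS = {
    "input",
    "simulate",
    "qc",
    "roh",
    "inbreeding",
    "landscape",
    "sweep",
    "ne",
    "assoc",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class ConfigError(ValueError):
    pass


def load_config(path) -> dict[str, Any]:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    unknown = set(cfg) - KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _known_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    frame.to_csv(tmp, sep="\t", index=False, float_format="%.10g")
    tmp.rename(path)


def run_pipeline(config: dict[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the run manifest (also written).

    ``config`` is a TOML path or an already-parsed dict with sections among
    ``input, simulate, qc, roh, inbreeding, landscape, sweep, ne, assoc``.
    Either ``[input]`` (ped/map or vcf paths) or ``[simulate]`` must be
    present.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        unknown = set(config) - KNOWN_SECTIONS
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "rohscape",
        "version": __version__,
        "stages": {},
        "inputs": {},
        "parameters": {},
    }

    def stage(name):
        def deco(fn):
            def wrapper(*a, **kw):
                t0 = time.time()
                log.info("stage %s: start", name)
                try:
                    result = fn(*a, **kw)
                except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                    raise PipelineError(name, exc) from exc
                manifest["stages"].setdefault(name, {})["wall_s"] = round(
                    time.time() - t0, 3
                )
                log.info("stage %s: done in %.2fs", name, time.time() - t0)
                return result

            return wrapper

        return deco

    # ---- input / simulate ------------------------------------------------
    pheno = None
    truth = None
    if "simulate" in config:
        sec = dict(config["simulate"])
        _known_keys(
            sec,
            {f.name for f in dataclasses.fields(SimConfig)}
            | {"phenotype_beta", "phenotype_marker", "phenotype_noise_sd"},
            "simulate",
        )
        plan = sec.pop("roh_plan", None)
        beta = sec.pop("phenotype_beta", None)
        ph_marker = sec.pop("phenotype_marker", None)
        ph_sd = sec.pop("phenotype_noise_sd", 3.0)
        if plan is not None:
            sec["roh_plan"] = tuple(
                RohPlanItem(int(length), count=int(count)) for length, count in plan
            )
        sim_cfg = SimConfig(**sec)

        @stage("simulate")
        def _simulate():
            m, t = simulate_dataset(sim_cfg)
            return m, t

        matrix, truth = _simulate()
        manifest["parameters"]["simulate"] = {
            **{
                k: v
                for k, v in dataclasses.asdict(sim_cfg).items()
                if k != "roh_plan"
            },
            "roh_plan": [dataclasses.asdict(p) for p in sim_cfg.roh_plan],
            "rng": truth.rng_algorithm,
        }
        manifest["stages"]["simulate"]["n_samples"] = matrix.n_samples
        manifest["stages"]["simulate"]["n_markers"] = matrix.n_markers
        if beta is not None:
            marker = ph_marker or matrix.markers["marker_id"].iloc[matrix.n_markers // 2]
            pheno, _ptruth, extras = simulate_phenotypes(
                matrix, marker, float(beta), noise_sd=float(ph_sd), seed=sim_cfg.seed + 2
            )
            write_phenotypes(pheno, out / "sim.pheno.tsv")
            manifest["parameters"]["simulate"]["phenotype"] = {
                "marker": str(marker),
                "beta": float(beta),
                "noise_sd": float(ph_sd),
                **extras,
            }
        write_ped_map(matrix, out / "sim.ped", out / "sim.map")
        _write_tsv(truth.planted_segments, out / "sim.truth.tsv")
    elif "input" in config:
        sec = dict(config["input"])
        _known_keys(sec, {"ped", "map", "vcf", "phenotypes"}, "input")

        @stage("input")
        def _load():
            if "vcf" in sec:
                m = read_vcf(sec["vcf"])
            elif "ped" in sec and "map" in sec:
                m = read_ped_map(sec["ped"], sec["map"])
            else:
                raise ConfigError("[input] needs either vcf or ped+map")
            return m

        matrix = _load()
        for key in ("ped", "map", "vcf", "phenotypes"):
            if key in sec:
                manifest["inputs"][key] = {
                    "path": str(sec[key]),
                    "sha256": _sha256(Path(sec[key])),
                }
        if "phenotypes" in sec:
            pheno = read_phenotypes(sec["phenotypes"])
    else:
        raise ConfigError("config needs an [input] or [simulate] section")

    # ---- qc --------------------------------------------------------------
    sec = dict(config.get("qc", {}))
    if sec.pop("skip", False):
        report = None
    else:
        _known_keys(sec, {f.name for f in dataclasses.fields(QCParams)}, "qc")
        params = QCParams(**sec)

        @stage("qc")
        def _qc():
            return apply_qc(matrix, params)

        matrix, report = _qc()
        manifest["parameters"]["qc"] = dataclasses.asdict(params)
        manifest["stages"]["qc"].update(
            {k: v for k, v in dataclasses.asdict(report).items() if k != "params"}
        )

    # ---- roh -------------------------------------------------------------
    sec = dict(config.get("roh", {}))
    skip_roh = sec.pop("skip", False)
    segments = pd.DataFrame()
    if not skip_roh:
        _known_keys(sec, {f.name for f in dataclasses.fields(ROHParams)}, "roh")
        rparams = ROHParams(**sec)

        @stage("roh")
        def _roh():
            return detect_roh(matrix, rparams)

        segments = _roh()
        manifest["parameters"]["roh"] = dataclasses.asdict(rparams)
        manifest["parameters"]["roh"]["min_snp_count_resolved"] = resolve_min_snp_count(
            matrix, rparams
        )
        manifest["stages"]["roh"]["n_segments"] = len(segments)
        _write_tsv(segments, out / "roh.tsv")

    # ---- inbreeding ------------------------------------------------------
    sec = dict(config.get("inbreeding", {}))
    if not sec.pop("skip", False) and not skip_roh:
        _known_keys(sec, {"l_auto_bp"}, "inbreeding")
        l_auto = int(sec.get("l_auto_bp", DEFAULT_L_AUTO_BP))

        @stage("inbreeding")
        def _inb():
            table = inbreeding_table(matrix, segments, l_auto)
            corr = None
            if len(table) >= 3:
                corr, _p = correlate_inbreeding(table)
            return table, corr

        table, corr = _inb()
        manifest["parameters"]["inbreeding"] = {"l_auto_bp": l_auto}
        manifest["stages"]["inbreeding"]["n_individuals"] = len(table)
        _write_tsv(table, out / "inbreeding.tsv")
        if corr is not None:
            _write_tsv(corr.reset_index(names="variable"), out / "inbreeding_corr.tsv")

    # ---- landscape -------------------------------------------------------
    sec = dict(config.get("landscape", {}))
    if not sec.pop("skip", False) and not skip_roh:
        _known_keys(
            sec, {"threshold", "flank_bp", "qtl_bed", "qtl_max_length_bp"}, "landscape"
        )
        threshold = float(sec.get("threshold", 0.80))
        flank_bp = int(sec.get("flank_bp", 50_000))

        @stage("landscape")
        def _land():
            tracks = {
                pop: occurrence(sub, segments) for pop, sub in matrix.by_population().items()
            }
            hotspots = {pop: call_hotspots(t, threshold) for pop, t in tracks.items()}
            cold = call_coldspots(list(tracks.values()))
            return tracks, hotspots, cold

        tracks, hotspots, cold = _land()
        manifest["parameters"]["landscape"] = {
            "threshold": threshold,
            "flank_bp": flank_bp,
        }
        for pop, t in tracks.items():
            _write_tsv(t, out / f"occurrence.{pop}.tsv")
        all_hot = []
        for pop, h in hotspots.items():
            h = h.assign(population=pop)
            all_hot.append(h)
            write_intervals(h, out / f"hotspots.{pop}.bed")
        write_intervals(cold, out / "coldspots.bed")
        manifest["stages"]["landscape"]["n_hotspots"] = int(
            sum(len(h) for h in hotspots.values())
        )
        manifest["stages"]["landscape"]["n_coldspots"] = len(cold)
        if "qtl_bed" in sec:
            qtl = read_intervals(sec["qtl_bed"])
            flanked = pd.concat(
                [flank_regions(h, flank_bp) for h in all_hot], ignore_index=True
            )
            overlaps = overlap_intervals(
                flanked, qtl, int(sec.get("qtl_max_length_bp", 1_000_000))
            )
            _write_tsv(overlaps, out / "qtl_overlaps.tsv")
            manifest["inputs"]["qtl_bed"] = {
                "path": str(sec["qtl_bed"]),
                "sha256": _sha256(Path(sec["qtl_bed"])),
            }

    # ---- sweep (pi / tajima / fst) --------------------------------------
    sec = dict(config.get("sweep", {}))
    if not sec.pop("skip", False):
        _known_keys(sec, {"window_bp", "step_bp"}, "sweep")
        window_bp = int(sec.get("window_bp", 500_000))
        step_bp = sec.get("step_bp")

        @stage("sweep")
        def _sweep():
            frames = []
            for pop, sub in matrix.by_population().items():
                pi = windowed_pi(sub, window_bp, step_bp)
                td = windowed_tajima_d(sub, window_bp, step_bp)
                f = pi.merge(
                    td[["chrom", "win_start_bp", "n_segregating", "n_chr", "tajima_d"]],
                    on=["chrom", "win_start_bp"],
                )
                f.insert(0, "population", pop)
                frames.append(f)
            result = pd.concat(frames, ignore_index=True)
            fst_summary = {}
            pops = matrix.by_population()
            if len(pops) == 2:
                (p1, m1), (p2, m2) = pops.items()
                fw, fst_summary = windowed_fst(m1, m2, window_bp, step_bp)
                fw.insert(0, "population", f"{p1}~{p2}")
                _write_tsv(fw, out / "fst_windows.tsv")
            return result, fst_summary

        sweep_frame, fst_summary = _sweep()
        manifest["parameters"]["sweep"] = {"window_bp": window_bp, "step_bp": step_bp}
        manifest["stages"]["sweep"]["n_windows"] = len(sweep_frame)
        manifest["stages"]["sweep"].update(fst_summary)
        _write_tsv(sweep_frame, out / "sweep.tsv")

    # ---- ne --------------------------------------------------------------
    sec = dict(config.get("ne", {}))
    if not sec.pop("skip", False):
        _known_keys(sec, {"bins_kb", "alpha_const", "maf_min"}, "ne")
        bins_kb = sec.get("bins_kb", [50, 100, 250, 500, 1000, 2000, 4000])
        alpha_const = float(sec.get("alpha_const", 2.2))
        maf_min = float(sec.get("maf_min", 0.05))

        @stage("ne")
        def _ne():
            return ne_ld(
                matrix, [int(b) * 1000 for b in bins_kb], alpha_const, maf_min
            )

        ne_frame = _ne()
        manifest["parameters"]["ne"] = {
            "bins_kb": list(bins_kb),
            "alpha_const": alpha_const,
            "maf_min": maf_min,
            "f_c": "c",
            "r2_adjustment": "r2 - 1/n",
            "t": "1/(2c)",
        }
        manifest["stages"]["ne"]["n_bins"] = len(ne_frame)
        _write_tsv(ne_frame, out / "ne.tsv")

    # ---- assoc -----------------------------------------------------------
    sec = dict(config.get("assoc", {}))
    if not sec.pop("skip", False) and sec:
        _known_keys(
            sec, {"marker", "covariates", "numeric_covariates", "effect_allele"}, "assoc"
        )
        if pheno is None:
            raise PipelineError("assoc", ValueError("no phenotype table available"))

        @stage("assoc")
        def _assoc():
            return linear_assoc(
                matrix,
                pheno,
                sec["marker"],
                covariates=tuple(sec.get("covariates", ("age", "batch"))),
                effect_allele=sec.get("effect_allele", "allele2"),
                numeric_covariates=bool(sec.get("numeric_covariates", False)),
            )

        result = _assoc()
        manifest["parameters"]["assoc"] = {
            "marker": sec["marker"],
            "covariates": list(sec.get("covariates", ("age", "batch"))),
            "numeric_covariates": bool(sec.get("numeric_covariates", False)),
        }
        manifest["stages"]["assoc"]["beta"] = result.beta
        manifest["stages"]["assoc"]["p"] = result.p_two_sided
        _write_tsv(result.to_frame(), out / "assoc.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
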