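"""The five-step estimation pipeline.

1. Frequency-domain phase correction of every direct-dimension slice
   (user-supplied p0/p1/pivot, or a coarse automatic zero-order search).
2. Per-region super-Gaussian filtering into sub-FIDs, optionally followed by
   frequency shift + decimation or truncation to cut estimation cost.
3. Per-region estimation: model order (MDL or manual) -> MMEMPM initial
   guess -> phase-regularized nonlinear refinement.
4. Region merging, multiplet grouping (threshold epsilon, default the
   digital resolution) and non-first-order purging.
5. Spectrum construction: pure shift spectrum, per-multiplet spectra,
   first-slice spectrum and residual, written with a full result record.

Every stochastic step (noise fill) draws its seed from the single config
seed through a spawned ``numpy.random.SeedSequence``, so a config re-run is
bit-reproducible.  All decisions (orders chosen, oscillators purged,
threshold used, deduplication) are logged and stored in the record's
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .bruker import read_bruker_2d
from .core import ExpInfo, FID2D, Oscillator2D, sort_oscillators
from .multiplets import default_threshold, group_multiplets, purge_non_first_order
from .optimize import FitConfig, fit
from .order import manual_order, mdl_order
from .pencil import mmempm
from .preprocess import (
    PhaseCorrection,
    Region,
    auto_phase0,
    baseline_sigma,
    decimate_subfid,
    filter_subfid,
    phase_correct,
    truncate_subfid,
)
from .results import ResultRecord, build_table, write_result
from .simulate import ArtifactSpec, SpinMultipletSpec, Synthetic2DJ, generate_2dj, sigma_for_snr
from .spectra import (
    first_slice_spectrum,
    multiplet_spectra,
    pure_shift_spectrum,
    residual_slice,
)

__all__ = ["PipelineConfig", "run_pipeline", "estimate_regions", "synthetic_from_config"]

logger = logging.getLogger("cupidnmr")


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline reproducibly.

    ``input_path`` names a Bruker-style directory; alternatively
    ``simulate`` holds a synthetic-data description (see
    :func:`synthetic_from_config`).  ``order`` is ``"auto"`` (MDL), an int
    applied to every region, or a per-region list.  ``epsilon`` is
    ``"auto"`` (digital resolution) or a value in Hz.  ``decimate`` is 1
    (off, the default), an integer factor, or ``"auto"`` (match the
    decimated sweep width to the region bandwidth; implies noise fill off,
    since the reduced band is then fully in-band).
    """

    input_path: str | None = None
    simulate: dict | None = None
    phase: tuple[float, float, float] | str | None = None  # (p0, p1, pivot) | "auto" | None
    regions: list[tuple[float, float]] | None = None
    region_units: str = "hz"  # "hz" | "ppm"
    order: int | str | list = "auto"
    epsilon: float | str = "auto"
    linkage: str = "single"
    sg_power: int = 40
    noise_fill: bool = True
    decimate: int | str = 1
    truncate: int | None = None
    phase_reg_weight: float | None = None
    global_refit: bool = True
    max_iter: int = 200
    purge_threshold: float = 1e-3
    lb: float = 0.0
    zf: int = 2
    seed: int = 0
    outdir: str | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.phase is not None and not isinstance(cfg.phase, str):
            cfg.phase = tuple(float(v) for v in cfg.phase)
        if cfg.regions is not None:
            cfg.regions = [tuple(float(v) for v in r) for r in cfg.regions]
        return cfg


def synthetic_from_config(sim: dict, seed: int | None = None) -> Synthetic2DJ:
    """Build a synthetic 2DJ data set from a config mapping.

    Keys: ``expinfo`` (points, dwell, offset, sfo), ``multiplets`` (list of
    fc / couplings / amplitude / eta1 / eta2 / phase), ``artifacts``
    (f1 / f2 / amplitude / ...), and either ``noise_sigma`` or ``snr_db``
    (the latter relative to the noiseless grid maximum).  ``seed`` overrides
    the mapping's own seed.
    """
    ei = sim["expinfo"]
    expinfo = ExpInfo(
        points=tuple(ei["points"]),
        dwell=tuple(ei["dwell"]),
        offset=tuple(ei.get("offset", (0.0, 0.0))),
        sfo=ei.get("sfo"),
    )
    specs = [
        SpinMultipletSpec(
            fc=float(m["fc"]),
            couplings=tuple((float(j), int(k)) for j, k in m.get("couplings", [])),
            amplitude=float(m.get("amplitude", 1.0)),
            eta1=float(m.get("eta1", 1.0)),
            eta2=float(m.get("eta2", 3.0)),
            phase=float(m.get("phase", 0.0)),
        )
        for m in sim.get("multiplets", [])
    ]
    artifacts = [
        ArtifactSpec(
            f1=float(a["f1"]),
            f2=float(a["f2"]),
            amplitude=float(a["amplitude"]),
            phase=float(a.get("phase", 0.0)),
            eta1=float(a.get("eta1", 1.0)),
            eta2=float(a.get("eta2", 3.0)),
        )
        for a in sim.get("artifacts", [])
    ]
    use_seed = sim.get("seed") if seed is None else seed
    if "noise_sigma" in sim:
        sigma = float(sim["noise_sigma"])
    elif "snr_db" in sim:
        noiseless = generate_2dj(specs, artifacts, expinfo, 0.0, None)
        sigma = sigma_for_snr(noiseless.fid, float(sim["snr_db"]))
    else:
        sigma = 0.0
    return generate_2dj(specs, artifacts, expinfo, sigma, use_seed)


def _regions_to_hz(cfg: PipelineConfig, expinfo: ExpInfo) -> list[Region]:
    if not cfg.regions:
        sw2 = expinfo.sweep_widths[1]
        logger.warning("no regions specified; using the whole sweep width as one region")
        return [Region(sw2 / 2 * 0.999, -sw2 / 2 * 0.999)]
    out = []
    for left, right in cfg.regions:
        if cfg.region_units == "ppm":
            if expinfo.sfo is None:
                raise ValueError("ppm regions need a spectrometer frequency (sfo)")
            left = left * expinfo.sfo - expinfo.offset[1]
            right = right * expinfo.sfo - expinfo.offset[1]
        elif cfg.region_units != "hz":
            raise ValueError(f"region_units must be 'hz' or 'ppm', got {cfg.region_units!r}")
        out.append(Region(left, right))
    return out


def _auto_decimation(region: Region, expinfo: ExpInfo) -> int:
    sw2 = expinfo.sweep_widths[1]
    # keep the reduced sweep width at least twice the region bandwidth (so
    # the filter's transition edges stay unaliased with margin) and keep at
    # least ~64 direct points (so the singular spectrum stays informative
    # for model-order selection)
    return max(1, min(int(sw2 / (2.0 * region.bandwidth)), expinfo.points[1] // 64))


def _resolve_order(cfg: PipelineConfig, n_regions: int) -> list:
    if isinstance(cfg.order, list):
        if len(cfg.order) != n_regions:
            raise ValueError(
                f"order list has {len(cfg.order)} entries for {n_regions} region(s)"
            )
        return cfg.order
    return [cfg.order] * n_regions


def estimate_regions(
    fid: FID2D, cfg: PipelineConfig
) -> tuple[list[Oscillator2D], np.ndarray | None, dict]:
    """Steps 2-3 plus region merging; returns oscillators, errors and a log dict.

    ``fid`` must already be phase corrected.  Oscillator parameters are
    reported in the absolute (carrier-relative) frame regardless of any
    per-region shift/decimation.
    """
    regions = _regions_to_hz(cfg, fid.expinfo)
    orders = _resolve_order(cfg, len(regions))
    seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(cfg.seed).spawn(len(regions))
    ]
    diag: dict = {"regions": [], "software": f"cupidnmr {_version}", "seed": cfg.seed}
    all_osc: list[Oscillator2D] = []
    all_err: list[np.ndarray] = []
    region_of: list[int] = []
    for i, (region, order, seed) in enumerate(zip(regions, orders, seeds)):
        rlog: dict = {"region_hz": [region.left, region.right], "seed": seed}
        factor = _auto_decimation(region, fid.expinfo) if cfg.decimate == "auto" else int(cfg.decimate)
        noise_fill = cfg.noise_fill and factor == 1
        full_sub = filter_subfid(fid, region, cfg.sg_power, noise_fill=noise_fill, seed=seed)
        sub, shift = full_sub, 0.0
        if factor > 1:
            sigma = baseline_sigma(fid, region, cfg.sg_power) if cfg.noise_fill else None
            sub, shift = decimate_subfid(full_sub, region, factor, cfg.sg_power, sigma, seed)
        if cfg.truncate is not None:
            sub = truncate_subfid(sub, int(cfg.truncate))
        rlog.update(decimate=factor, noise_fill=noise_fill, shift_hz=shift)
        if order == "auto":
            est = mdl_order(sub.first_slice())
        else:
            est = manual_order(int(order))
        n1s, n2s = sub.expinfo.points
        l1, l2 = max(2, n1s // 3), max(2, n2s // 3)
        m_max = min((l1 - 1) * l2, l1 * (l2 - 1)) - 1
        m = min(est.M, m_max)
        rlog.update(order=m, order_method=est.method)
        if m != est.M:
            logger.warning("region %d: order %d capped at rank bound %d", i, est.M, m)
        if m == 0:
            logger.warning("region %d (%s): model order 0, no signals estimated", i, region)
            diag["regions"].append(rlog)
            continue
        init = mmempm(sub, m)
        halfwidth = 0.75 * region.bandwidth
        fit_cfg = FitConfig(
            phase_reg_weight=cfg.phase_reg_weight,
            max_iter=cfg.max_iter,
            purge_threshold=cfg.purge_threshold,
            f2_bounds=(region.center - shift, halfwidth),
        )
        osc, report = fit(sub, init, fit_cfg)
        if shift:
            osc = [
                Oscillator2D(o.amplitude, o.phase, o.f1, o.f2 + shift, o.eta1, o.eta2)
                for o in osc
            ]
        if factor > 1 and osc:
            # refine on the undecimated filtered sub-FID: the decimated grid
            # carries synthetic fill noise, the full one all in-band signal
            refine_cfg = FitConfig(
                phase_reg_weight=cfg.phase_reg_weight,
                max_iter=cfg.max_iter,
                purge_threshold=cfg.purge_threshold,
                f2_bounds=(region.center, halfwidth),
            )
            osc, report = fit(full_sub, osc, refine_cfg)
        rlog.update(
            initial_cost=report.initial_cost,
            final_cost=report.final_cost,
            iterations=report.iterations,
            converged=report.converged,
            n_purged_lowamp=len(report.purged),
        )
        errs = report.param_errors if report.param_errors is not None else np.full((len(osc), 6), np.nan)
        all_osc.extend(osc)
        all_err.append(errs)
        region_of.extend([i] * len(osc))
        diag["regions"].append(rlog)

    errors = np.vstack(all_err) if all_err else np.empty((0, 6))
    # deduplicate overlapping-region copies: same line estimated twice
    eps = default_threshold(fid.expinfo) if cfg.epsilon == "auto" else float(cfg.epsilon)
    res2 = 1.0 / (fid.expinfo.dwell[1] * fid.expinfo.points[1])
    keep = np.ones(len(all_osc), dtype=bool)
    for a in range(len(all_osc)):
        if not keep[a]:
            continue
        for b in range(a + 1, len(all_osc)):
            if not keep[b] or region_of[a] == region_of[b]:
                continue
            oa, ob = all_osc[a], all_osc[b]
            if abs(oa.f2 - ob.f2) < res2 and abs(oa.f1 - ob.f1) < eps:
                ca = regions[region_of[a]].center
                cb = regions[region_of[b]].center
                drop = b if abs(ob.f2 - cb) >= abs(oa.f2 - ca) else a
                keep[drop] = False
                logger.info("deduplicated oscillator from region %d", region_of[drop])
    merged = [o for o, k in zip(all_osc, keep) if k]
    errors = errors[keep] if errors.size else errors
    merged_sorted = sort_oscillators(merged)
    # re-sort errors to match the sorted oscillator order
    if merged:
        perm = sorted(range(len(merged)), key=lambda j: (merged[j].f2, merged[j].f1))
        errors = errors[perm]
    diag["n_deduplicated"] = int((~keep).sum())
    diag["epsilon_hz"] = eps
    if cfg.global_refit and merged_sorted:
        # final polish against the raw (unfiltered) grid: removes the small
        # lineshape bias the band-pass filter leaves in per-region fits and
        # yields error bars calibrated against the true white noise floor
        refit_cfg = FitConfig(
            phase_reg_weight=cfg.phase_reg_weight,
            max_iter=cfg.max_iter,
            purge_threshold=cfg.purge_threshold,
        )
        merged_sorted, report = fit(fid, merged_sorted, refit_cfg)
        errors = (
            report.param_errors
            if report.param_errors is not None
            else np.full((len(merged_sorted), 6), np.nan)
        )
        diag["global_refit"] = {
            "final_cost": report.final_cost,
            "iterations": report.iterations,
            "converged": report.converged,
            "n_purged_lowamp": len(report.purged),
        }
    return merged_sorted, errors, diag


def run_pipeline(cfg: PipelineConfig) -> ResultRecord:
    """Execute the full pipeline and (optionally) write results and spectra."""
    stage = "input"
    try:
        truth = None
        if cfg.input_path is not None:
            fid = read_bruker_2d(cfg.input_path)
        elif cfg.simulate is not None:
            truth = synthetic_from_config(cfg.simulate, seed=cfg.simulate.get("seed", cfg.seed))
            fid = truth.fid
        else:
            raise ValueError("config must provide input_path or simulate")

        stage = "phase_correction"
        if cfg.phase == "auto":
            pc = auto_phase0(fid)
            logger.info("auto phase correction: p0 = %.4f rad", pc.p0)
        elif cfg.phase is not None:
            pc = PhaseCorrection(*cfg.phase)
        else:
            pc = None
        if pc is not None:
            fid = phase_correct(fid, pc)

        stage = "estimation"
        oscillators, errors, diag = estimate_regions(fid, cfg)

        stage = "multiplet_identification"
        eps = diag["epsilon_hz"]
        mps = group_multiplets(oscillators, eps, cfg.linkage)
        kept, purge_report = purge_non_first_order(oscillators, mps, eps)
        kept_mps = group_multiplets(kept, eps, cfg.linkage)
        multiplet_ids = np.full(len(oscillators), -1, dtype=int)
        kept_idx = [i for i in range(len(oscillators)) if i not in set(purge_report.purged)]
        for mid, m in enumerate(kept_mps):
            for member in m.members:
                multiplet_ids[kept_idx[member]] = mid
        purged_flags = [i in set(purge_report.purged) for i in range(len(oscillators))]
        reasons = ["; ".join(purge_report.criteria.get(i, [])) for i in range(len(oscillators))]
        logger.info(
            "grouped %d oscillators into %d multiplets (epsilon %.4g Hz); purged %d",
            len(kept), len(kept_mps), eps, len(purge_report.purged),
        )

        stage = "spectrum_construction"
        table = build_table(oscillators, errors, list(multiplet_ids), purged_flags, reasons)
        record = ResultRecord(
            table=table,
            expinfo=fid.expinfo,
            regions=[tuple(r) for r in (cfg.regions or [])],
            processing={
                "lb_hz": cfg.lb,
                "zf": cfg.zf,
                "sg_power": cfg.sg_power,
                "noise_fill": cfg.noise_fill,
                "decimate": cfg.decimate,
                "truncate": cfg.truncate,
                "linkage": cfg.linkage,
            },
            provenance={
                "epsilon_hz": eps,
                "phase": list(cfg.phase) if isinstance(cfg.phase, tuple) else cfg.phase,
                "estimation": diag,
                "purged_indices": purge_report.purged,
                "software": f"cupidnmr {_version}",
            },
        )
        if cfg.outdir is not None:
            out = Path(cfg.outdir)
            out.mkdir(parents=True, exist_ok=True)
            write_result(record, out / "result")
            ps = pure_shift_spectrum(kept, fid.expinfo, cfg.lb, cfg.zf)
            ps.to_text(out / "pure_shift.txt")
            first_slice_spectrum(fid, cfg.lb, cfg.zf).to_text(out / "first_slice.txt")
            residual_slice(fid, oscillators, cfg.lb, cfg.zf).to_text(out / "residual.txt")
            for i, spec in enumerate(multiplet_spectra(kept, kept_mps, fid.expinfo, cfg.lb, cfg.zf)):
                spec.to_text(out / f"multiplet_{i:02d}.txt")
            if cfg.plots:
                _plot_summary(out, kept, kept_mps, fid, cfg)
        return record
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _plot_summary(out: Path, kept, kept_mps, fid: FID2D, cfg: PipelineConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(8, 8), sharex=True)
    ps = pure_shift_spectrum(kept, fid.expinfo, cfg.lb, cfg.zf)
    axes[0].plot(ps.axis_hz, ps.intensity, lw=0.8)
    axes[0].set_ylabel("pure shift")
    fs = first_slice_spectrum(fid, cfg.lb, cfg.zf)
    axes[1].plot(fs.axis_hz, fs.intensity, lw=0.8)
    axes[1].set_ylabel("first slice")
    for spec in multiplet_spectra(kept, kept_mps, fid.expinfo, cfg.lb, cfg.zf):
        axes[2].plot(spec.axis_hz, spec.intensity, lw=0.8)
    axes[2].set_ylabel("multiplets")
    axes[2].set_xlabel("frequency (Hz)")
    for ax in axes:
        ax.invert_xaxis() if ax.get_xlim()[0] < ax.get_xlim()[1] else None
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=150)
    plt.close(fig)
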