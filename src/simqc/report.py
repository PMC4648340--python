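"""Batch runner: run the default check suite and summarize metric quality.

Each executed check yields a :class:`CheckReport` of named metrics, a quality
tier per metric (``ok`` / ``caution`` / ``concern``) derived purely from the
configurable thresholds below, a short guidance string and the paths of any
rendered artifacts.  QC is advisory: a "concern" tier never fails the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rawchecks, reconchecks
from .hyperstack import RawSIMStack, ReconStack, SimqcError

logger = logging.getLogger("simqc")

#: Configurable tier thresholds.  ``higher_is_worse`` metrics go to caution /
#: concern above the two bounds; others below them.  These defaults are
#: package choices meant as starting points, not instrument standards.
DEFAULT_THRESHOLDS = {
    "tiv_pct": {"caution": 30.0, "concern": 50.0, "higher_is_worse": True},
    "decay_pct": {"caution": 20.0, "concern": 40.0, "higher_is_worse": True},
    "max_angle_diff_pct": {"caution": 15.0, "concern": 30.0,
                           "higher_is_worse": True},
    "flicker_pct": {"caution": 15.0, "concern": 30.0, "higher_is_worse": True},
    "feature_mean_mcnr": {"caution": 8.0, "concern": 4.0,
                          "higher_is_worse": False},
    "mmr": {"caution": 6.0, "concern": 3.0, "higher_is_worse": False},
    "zmv": {"caution": 0.1, "concern": 0.3, "higher_is_worse": True},
}

GUIDANCE = {
    "cip": "Large intensity swings in the central window degrade the "
           "reconstruction; check bleaching, angle balance and illumination "
           "stability.",
    "fpj": "First/second-order spots per angle indicate a well-calibrated "
           "stripe pattern; missing or weak spots suggest calibration or "
           "contrast problems.",
    "miv": "Coloured sub-regions in the merge indicate motion or uneven "
           "illumination between angles; grey-white means stable data.",
    "mcn": "Low feature MCNR limits recoverable super-resolution "
           "information; consider the suggested Wiener constant.",
    "rih": "A low min-to-max ratio means reconstructed noise/ringing is "
           "comparable to features; requires full-range input.",
    "sam": "Elevated ZMV indicates OTF mismatch (spherical aberration or "
           "pattern-focus offset).",
    "ftl": "Inspect the lateral spectrum and radial profile for frequency "
           "support and atypical patterns.",
    "fto": "Inspect the axial spectrum for z-direction frequency support.",
    "mcm": "Purple features sit on low raw modulation contrast and may be "
           "reconstruction noise; green marks raw saturation.",
}


@dataclass
class CheckReport:
    """Outcome of one check: metrics, tiers, guidance and artifacts."""

    check_id: str
    metrics: dict = field(default_factory=dict)     # name -> value
    units: dict = field(default_factory=dict)       # name -> unit string
    tiers: dict = field(default_factory=dict)       # name -> tier
    guidance: str = ""
    artifacts: list = field(default_factory=list)


def tier_for(name, value, thresholds=None):
    """Quality tier of one metric value under the configured thresholds."""
    spec = (thresholds or DEFAULT_THRESHOLDS).get(name)
    if spec is None or value is None or not np.isfinite(value):
        return "ok"
    if spec["higher_is_worse"]:
        if value >= spec["concern"]:
            return "concern"
        if value >= spec["caution"]:
            return "caution"
    else:
        if value <= spec["concern"]:
            return "concern"
        if value <= spec["caution"]:
            return "caution"
    return "ok"


def _report(check_id, metrics, units, thresholds):
    tiers = {k: tier_for(k, v, thresholds) for k, v in metrics.items()}
    return CheckReport(check_id=check_id, metrics=metrics, units=units,
                       tiers=tiers, guidance=GUIDANCE.get(check_id, ""))


def _save_image(path, img):
    import matplotlib.pyplot as plt

    plt.imsave(path, np.clip(img, 0, 1) if img.ndim == 3 else img,
               cmap=None if img.ndim == 3 else "gray")
    return str(path)


def run_all(raw: RawSIMStack | None = None, recon: ReconStack | None = None,
            config: dict | None = None, out_dir=None):
    """Run the default check suite on the given stacks.

    Raw checks: intensity profile, motion/illumination variation and
    modulation contrast (plus the Fourier projection when enabled).  Recon
    checks: intensity histogram and the lateral + axial Fourier plots (plus
    the aberration-mismatch check when enabled); the modulation contrast map
    runs when both stacks are given.  The Fourier projection and the
    aberration check are off by default — they need specific sample types.

    Returns ``(reports, summary)`` where ``summary`` is a DataFrame with one
    row per executed check.  When ``out_dir`` is given, writes
    ``summary.csv``, ``simqc.log`` and per-check artifacts there.
    """
    if raw is None and recon is None:
        raise SimqcError("provide a raw and/or a reconstructed stack")
    cfg = dict(config or {})
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    reports: list[CheckReport] = []
    log_lines: list[str] = []
    mcnr_result = None

    def add(rep):
        reports.append(rep)
        parts = ", ".join(f"{k}={v:.4g}{(' ' + rep.units.get(k, '')).rstrip()}"
                          f" [{rep.tiers[k]}]" for k, v in rep.metrics.items())
        log_lines.append(f"{rep.check_id}: {parts or 'see artifacts'}")
        if rep.guidance:
            log_lines.append(f"  {rep.guidance}")

    if raw is not None:
        cip = rawchecks.channel_intensity_profile(raw)
        rep = _report("cip", {
            "tiv_pct": float(cip.tiv.max()),
            "decay_pct": float(cip.decay.max()),
            "max_angle_diff_pct": float(cip.max_angle_diff.max()),
            "flicker_pct": float(cip.flicker.max()),
        }, {k: "%" for k in ("tiv_pct", "decay_pct", "max_angle_diff_pct",
                             "flicker_pct")}, thresholds)
        if out is not None:
            rep.artifacts.append(str(cip.plot(out / "cip_profile.png")))
        add(rep)

        if cfg.get("fpj", False):
            fpj = rawchecks.raw_fourier_projection(raw)
            rep = _report("fpj", {}, {}, thresholds)
            if out is not None:
                for c in range(fpj.shape[0]):
                    rep.artifacts.append(
                        _save_image(out / f"fpj_c{c}.png", fpj[c]))
            add(rep)

        miv = rawchecks.motion_illumination_variation(raw)
        rep = _report("miv", {}, {}, thresholds)
        if out is not None:
            zc = miv.rgb.shape[1] // 2
            for c in range(miv.rgb.shape[0]):
                rep.artifacts.append(
                    _save_image(out / f"miv_c{c}.png", miv.rgb[c, zc]))
        add(rep)

        mcnr_result = rawchecks.mcnr(raw, zw=int(cfg.get("zw", 1)))
        rep = _report("mcn", {
            "feature_mean_mcnr": float(np.min(mcnr_result.feature_mean_mcnr)),
            "wiener_suggestion": float(np.max(mcnr_result.wiener_suggestion)),
        }, {"feature_mean_mcnr": "", "wiener_suggestion": ""}, thresholds)
        if out is not None:
            zc = mcnr_result.mcnr_map.shape[1] // 2
            for c in range(mcnr_result.mcnr_map.shape[0]):
                img = np.nan_to_num(mcnr_result.mcnr_map[c, zc],
                                    posinf=reconchecks.MCNR_DISPLAY_MAX)
                rep.artifacts.append(_save_image(
                    out / f"mcn_c{c}.png",
                    np.clip(img / reconchecks.MCNR_DISPLAY_MAX, 0, 1)))
        add(rep)

    if recon is not None:
        rih = reconchecks.reconstructed_intensity_histogram(recon)
        rep = _report("rih", {"mmr": float(np.nanmin(rih.mmr)),
                              "mode": float(rih.mode[0])},
                      {"mmr": "", "mode": ""}, thresholds)
        if out is not None:
            rep.artifacts.append(str(rih.plot(out / "rih_histogram.png")))
        add(rep)

        if cfg.get("sam", False):
            sam = reconchecks.spherical_aberration_mismatch(recon)
            rep = _report("sam", {"zmv": float(sam.zmv.max())}, {"zmv": ""},
                          thresholds)
            if out is not None:
                rep.artifacts.append(str(sam.plot(out / "sam_profile.png")))
            add(rep)

        opts = reconchecks.FourierOptions(cutoff=cfg.get("cutoff", "auto"),
                                          window=bool(cfg.get("window", False)),
                                          log_power=bool(cfg.get("log_power",
                                                                 False)))
        fps = reconchecks.fourier_plots(recon, opts)
        rep = _report("ftl", {}, {}, thresholds)
        if out is not None:
            rep.artifacts.append(str(fps.plot(out / "ftl.png")))
        add(rep)
        rep = _report("fto", {}, {}, thresholds)
        if out is not None:
            lo, hi = fps.options.display_range
            img = np.clip((fps.fto[0] - lo) / (hi - lo), 0, 1)
            rep.artifacts.append(_save_image(out / "fto.png", img))
        add(rep)

    if raw is not None and recon is not None:
        mcm = reconchecks.modulation_contrast_map(recon, mcnr_result, raw)
        rep = _report("mcm", {}, {}, thresholds)
        if out is not None:
            zc = mcm.rgb.shape[1] // 2
            for c in range(mcm.rgb.shape[0]):
                rep.artifacts.append(
                    _save_image(out / f"mcm_c{c}.png", mcm.rgb[c, zc]))
        add(rep)

    rows = []
    for rep in reports:
        if rep.metrics:
            for k, v in rep.metrics.items():
                rows.append({"check": rep.check_id, "metric": k, "value": v,
                             "units": rep.units.get(k, ""),
                             "tier": rep.tiers[k]})
        else:
            rows.append({"check": rep.check_id, "metric": "", "value": np.nan,
                         "units": "", "tier": "ok"})
    summary = pd.DataFrame(rows, columns=["check", "metric", "value", "units",
                                          "tier"])
    if out is not None:
        summary.to_csv(out / "summary.csv", index=False)
        (out / "simqc.log").write_text("\n".join(log_lines) + "\n")
        metrics_json = {
            rep.check_id: {k: (None if not np.isfinite(v) else v)
                           for k, v in rep.metrics.items()}
            for rep in reports}
        (out / "metrics.json").write_text(json.dumps(metrics_json, indent=1))
    return reports, summary
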