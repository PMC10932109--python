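"""End-to-end orchestration: from a SEC-SANS run (or bare curves) to a
per-fraction report of Guinier, P(r), Kratky, elliptical-cylinder fit and
optional ab initio reconstruction — the analysis chain a fraction would
pass through after peak separation."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import abinitio
from .curves import ScatteringCurve, compute_kratky
from .formfactor import fit_model
from .guinier import GuinierResult, fit_guinier
from .ift import compute_pr, rg_from_pr, scan_dmax
from .synth import SECSANSRun, average_peak, peak_frame_range, scattergram

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Per-stage knobs for the standard analysis chain.

    ``dmax_span`` sets the Dmax candidate grid as multiples of the Guinier Rg;
    ``recon_q_cut`` restricts reconstruction inputs to low Q where bead models
    are meaningful; reconstruction runs (off by default, 5 runs when enabled,
    20 in full mode) use coarse beads sized by ``recon_bead_fraction * dmax``.
    """

    qrg_limit: float = 1.3
    dmax_span: tuple[float, float, int] = (2.6, 4.6, 11)
    fit_q_max: float | None = None
    recon_enabled: bool = False
    recon_runs: int = 5
    recon_q_cut: float = 0.13
    recon_bead_fraction: float = 1.0 / 18.0
    seed: int = 0
    peak_width_sigmas: float = 1.0


@dataclass
class FractionReport:
    """Per-fraction results mirroring a published analysis table."""

    label: str
    guinier: dict | None = None
    pr: dict | None = None
    kratky_class: str | None = None
    cylinder_fit: dict | None = None
    reconstruction: dict | None = None
    errors: dict = field(default_factory=dict)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item(), ndigits)
    return obj


def analyze_fraction(curve: ScatteringCurve, label: str, config: PipelineConfig) -> FractionReport:
    """Run the full per-fraction chain, capturing stage errors individually."""
    rep = FractionReport(label=label)
    t0 = time.perf_counter()

    gres: GuinierResult | None = None
    try:
        gres = fit_guinier(curve, qrg_limit=config.qrg_limit)
        rep.guinier = {
            "rg": gres.rg,
            "i0": gres.i0,
            "window": list(gres.window),
            "qrg_bounds": list(gres.qrg_bounds),
            "fit_quality": gres.fit_quality,
        }
    except Exception as exc:  # noqa: BLE001 - per-stage capture is the contract
        rep.errors["guinier"] = str(exc)
    log.info("%s: guinier done (%.2fs)", label, time.perf_counter() - t0)

    pr = None
    best = None
    try:
        rg_guess = gres.rg if gres is not None else 25.0
        lo, hi, n = config.dmax_span
        candidates = np.linspace(lo, hi, int(n)) * rg_guess
        best, diags = scan_dmax(curve, candidates)
        pr = compute_pr(curve, best)
        rg_pr, i0_pr = rg_from_pr(pr)
        rep.pr = {
            "dmax": best,
            "rg": rg_pr,
            "i0": i0_pr,
            "alpha": pr.alpha,
            "fit_chi2": pr.fit_chi2,
        }
    except Exception as exc:  # noqa: BLE001
        rep.errors["pr"] = str(exc)
    log.info("%s: P(r) done (%.2fs)", label, time.perf_counter() - t0)

    try:
        rep.kratky_class = compute_kratky(curve).classification.value
    except Exception as exc:  # noqa: BLE001
        rep.errors["kratky"] = str(exc)

    try:
        rg = gres.rg if gres is not None else 25.0
        dmax = best if best is not None else 3.5 * rg
        bounds = {
            "minor_radius": (2.0, 60.0),
            "axis_ratio": (1.0, 6.0),
            "length": (10.0, 300.0),
            "scale": (1e-9, np.inf),
        }
        scale0 = float(gres.i0 if gres is not None else curve.intensity[0])
        # the (length, axis-ratio) landscape is multimodal on noisy smeared
        # data: deterministic multi-start, keep the best reduced chi^2
        fit = None
        for nu0 in (1.5, 2.0, 3.0):
            for frac in (0.6, 0.8):
                L0 = frac * dmax
                a2 = max((rg**2 - L0**2 / 12.0) * 4.0 / (1.0 + nu0**2), 4.0)
                init = {
                    "minor_radius": float(np.sqrt(a2)),
                    "axis_ratio": nu0,
                    "length": L0,
                    "scale": scale0,
                }
                try:
                    cand = fit_model(curve, "elliptical_cylinder", init, bounds)
                except (RuntimeError, ValueError):
                    continue
                if fit is None or cand.reduced_chi2 < fit.reduced_chi2:
                    fit = cand
        if fit is None:
            raise RuntimeError("all cylinder-fit starts failed")
        rep.cylinder_fit = {
            "params": fit.params,
            "uncertainties": fit.uncertainties,
            "reduced_chi2": fit.reduced_chi2,
            "n_points": fit.n_points,
        }
    except Exception as exc:  # noqa: BLE001
        rep.errors["cylinder_fit"] = str(exc)
    log.info("%s: cylinder fit done (%.2fs)", label, time.perf_counter() - t0)

    if config.recon_enabled and best is not None:
        try:
            target = curve.restricted(qmax=config.recon_q_cut)
            symmetry = "P2" if label == "high_mw" else "P1"
            models = []
            for run_i in range(config.recon_runs):
                cfg = abinitio.AnnealConfig(seed=config.seed * 1000 + run_i)
                m = abinitio.reconstruct_shape(
                    target, best, symmetry=symmetry, config=cfg,
                    bead_radius=config.recon_bead_fraction * best,
                )
                models.append(m)
            aligned = abinitio.align_models(models)
            avg = abinitio.average_models(aligned)
            nsds = [
                abinitio.nsd(aligned[i], aligned[j])
                for i in range(len(aligned))
                for j in range(i + 1, len(aligned))
            ]
            rep.reconstruction = {
                "n_runs": config.recon_runs,
                "symmetry": symmetry,
                "n_beads_avg": len(avg),
                "mean_pairwise_nsd": float(np.mean(nsds)) if nsds else 0.0,
            }
        except Exception as exc:  # noqa: BLE001
            rep.errors["reconstruction"] = str(exc)
        log.info("%s: reconstruction done (%.2fs)", label, time.perf_counter() - t0)

    return rep


def run_pipeline(
    run_or_curves: SECSANSRun | ScatteringCurve | list[ScatteringCurve],
    config: PipelineConfig | None = None,
) -> list[FractionReport]:
    """Analyze a SEC-SANS run (peak extraction first) or pre-extracted curves.

    For a run, detected elution peaks become fractions labelled in elution
    order (``high_mw`` first — larger species elute earlier — then ``low_mw``,
    then ``custom``).  Deterministic given config seeds.
    """
    config = config or PipelineConfig()
    if isinstance(run_or_curves, SECSANSRun):
        run = run_or_curves
        sg = scattergram(run)
        labels = ["high_mw", "low_mw"]
        fractions = []
        for k, (center, sigma) in enumerate(zip(sg.peaks, sg.peak_sigmas)):
            frames = peak_frame_range(run, center, sigma, config.peak_width_sigmas)
            curve = average_peak(run, frames)
            label = labels[k] if k < len(labels) else f"custom_{k}"
            fractions.append((label, curve))
    elif isinstance(run_or_curves, ScatteringCurve):
        fractions = [("custom", run_or_curves)]
    else:
        fractions = [(c.label or f"custom_{i}", c) for i, c in enumerate(run_or_curves)]
    return [analyze_fraction(curve, label, config) for label, curve in fractions]


def report_to_json(reports: list[FractionReport]) -> str:
    """Stable JSON serialization (rounded floats, sorted keys)."""
    payload = [_round_floats(asdict(r)) for r in reports]
    return json.dumps(payload, indent=2, sort_keys=True)


def render_table(reports: list[FractionReport]) -> str:
    """Plain-text per-fraction summary table."""
    rows = [
        ("", [r.label for r in reports]),
        ("Guinier Rg (A)", [f"{r.guinier['rg']:.2f}" if r.guinier else "-" for r in reports]),
        ("Guinier I(0)", [f"{r.guinier['i0']:.4g}" if r.guinier else "-" for r in reports]),
        ("P(r) Rg (A)", [f"{r.pr['rg']:.2f}" if r.pr else "-" for r in reports]),
        ("P(r) I(0)", [f"{r.pr['i0']:.4g}" if r.pr else "-" for r in reports]),
        ("Dmax (A)", [f"{r.pr['dmax']:.0f}" if r.pr else "-" for r in reports]),
        ("Kratky", [r.kratky_class or "-" for r in reports]),
        ("Minor radius (A)", [
            f"{r.cylinder_fit['params']['minor_radius']:.2f}" if r.cylinder_fit else "-"
            for r in reports
        ]),
        ("Axis ratio", [
            f"{r.cylinder_fit['params']['axis_ratio']:.2f}" if r.cylinder_fit else "-"
            for r in reports
        ]),
        ("Length (A)", [
            f"{r.cylinder_fit['params']['length']:.2f}" if r.cylinder_fit else "-"
            for r in reports
        ]),
        ("chi^2", [
            f"{r.cylinder_fit['reduced_chi2']:.2f}" if r.cylinder_fit else "-"
            for r in reports
        ]),
    ]
    width = max(len(name) for name, _ in rows) + 2
    colw = 14
    lines = []
    for name, vals in rows:
        lines.append(name.ljust(width) + "".join(v.rjust(colw) for v in vals))
    return "\n".join(lines)
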