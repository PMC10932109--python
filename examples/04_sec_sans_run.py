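"""A full synthetic SEC-SANS experiment and its per-fraction analysis.

Simulates a two-species elution (an elongated and a compact particle with
partially overlapping peaks), detects the elution peaks in the scattergram,
extracts each fraction's peak-averaged curve, and runs the standard analysis
chain, printing a table analogous to a published per-fraction summary.
"""

from secsans import (
    fit_guinier,
    make_reference_components,
    peak_frame_range,
    average_peak,
    render_table,
    run_pipeline,
    scattergram,
    simulate_run,
)

high, low = make_reference_components("table1")
run = simulate_run([high, low], n_frames=60, background_level=0.002, noise_scale=0.005, seed=12)

sg = scattergram(run)
print(f"detected elution peaks at frames {[int(p) for p in sg.peaks]} (generated at 18 and 34)")

for (center, sigma), comp, label in zip(
    zip(sg.peaks, sg.peak_sigmas), (high, low), ("high-MW", "low-MW")
):
    frames = peak_frame_range(run, center, sigma)
    avg = average_peak(run, frames)
    rg = fit_guinier(avg).rg
    rg_ref = fit_guinier(comp.reference_curve).rg
    print(f"{label}: {len(frames)} frames averaged, Guinier Rg {rg:.2f} A (component: {rg_ref:.2f} A)")

print()
reports = run_pipeline(run)
print(render_table(reports))
print()
print("The elongated species elutes first and shows the larger Rg and Dmax;")
print("the cylinder fits recover the generating geometries from noisy frames.")
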