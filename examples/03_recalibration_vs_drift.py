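"""Visual recalibration keeps the grid pattern anchored under sensor noise.

Two 30-minute sessions with identical noisy sensors (1-degree compass
jitter plus a correlated compass error): one free-running, one with a
homing drive that returns the agent to the goal every minute and resets
the path-integration field there.  Gridness of the same modulo-9 phase
cell is compared.
"""
from gridpi.analysis import rate_map, gridness_from_rate_map
from gridpi.experiments import dominant_phase_activity, grid_session, preset

for label, preset_id, period in (("no recalibration", "exp1", None),
                                 ("1-min recalibration", "exp2", 60.0)):
    cfg = preset(preset_id, seed=0)
    result, pi, layers, arena = grid_session(cfg, recal_period=period)
    layer = layers[1]  # modulo 9
    act, _ = dominant_phase_activity(layer, result.d_history, pi.d_max)
    rmap = rate_map(result.trajectory.x, result.trajectory.y, act,
                    cfg.map_bin, cfg.map_smooth)
    score = gridness_from_rate_map(rmap).score
    print(f"{label:22s}: gridness {score:+.2f}  "
          f"({len(result.recal_steps)} recalibrations)")

print("Without recalibration the integrator drifts by roughly a lattice period")
print("every few minutes and the 30-minute map scrambles; the periodic visual")
print("reset bounds the drift and preserves the hexagonal pattern.")
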