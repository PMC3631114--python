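"""Bending-fatigue moduli and compression descriptors.

First builds a 300-cycle three-point-bending series whose peak force
decays by 5.7%, summarizes it with the secant modulus; then generates
one transverse (T) and one longitudinal (L) compression record and
extracts their descriptors with the direction-specific truncation rules.
"""

import numpy as np

import bonepore as bp

# fatigue: linear ramp cycles to 0.9 mm, force decaying 5.7% over 300 cycles
cycles = []
for k in range(300):
    d = np.linspace(0.0, 0.9, 40)
    peak = 30.0 * (1.0 - 0.057 * k / 299.0)
    cycles.append((d, peak * d / 0.9))
res = bp.fatigue_summary(bp.BendingCycleSeries(cycles, width_mm=10.0, height_mm=4.0))
print(f"M_first = {res.m_first_mpa:.1f} MPa, M_last = {res.m_last_mpa:.1f} MPa, "
      f"modulus drop = {res.percent_change:.1f}%")
# the drop quantifies fatigue damage accumulated over the cyclic loading

# compression: T fails at ~45% strain, L is analyzed at exactly 50% strain
t_rec = bp.compression_descriptors(bp.generate_compression_curve(
    bp.SyntheticCurveSpec(direction="T", failure_strain=0.45, noise_sd=0.3, seed=2)))
l_rec = bp.compression_descriptors(bp.generate_compression_curve(
    bp.SyntheticCurveSpec(direction="L", noise_sd=0.3, seed=3)))
print(f"T: ultimate stress {t_rec.ultimate_stress_mpa:.2f} MPa at strain "
      f"{t_rec.ultimate_strain:.2f}, work to failure {t_rec.work_to_failure_mj:.1f} mJ")
print(f"L: stress at 50% strain {l_rec.stress_at_50pct_mpa:.2f} MPa, "
      f"work to 50% strain {l_rec.work_at_50pct_mj:.1f} mJ")
# work is the trapezoidal area under the force-displacement curve (N*mm = mJ)
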