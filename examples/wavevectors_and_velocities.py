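"""Probed wave vectors for each scattering geometry, and shift-to-velocity conversion.

A 532 nm laser at theta = 90 deg in transmission probes q_par = 0.0167 1/nm
(independent of the refractive index); the reflection geometry at 120 deg with
n = 1.54 probes q_perp = 0.0344 1/nm; backscattering probes 4*pi*n/lambda.
A peak at 13.18 GHz on the q_par branch corresponds to c = 2*pi*f/q ~ 4960 m/s,
the longitudinal sound velocity along the silk fiber axis.
"""

from silkbls import ScatteringConfig, q_backscatter, q_reflection, q_transmission, velocity_from_shift

cfg = ScatteringConfig(wavelength_nm=532, theta_deg=90, n=1.54)

q_par = q_transmission(cfg)
q_perp = q_reflection(cfg.with_(theta_deg=120, geometry="reflection"))
q_bs = q_backscatter(cfg)

print(f"q_par  (transmission, 90 deg)   = {q_par.inv_nm:.4f} 1/nm")
print(f"q_perp (reflection, 120 deg)    = {q_perp.inv_nm:.4f} 1/nm")
print(f"q_bs   (backscattering leakage) = {q_bs.inv_nm:.5f} 1/nm")

f_axial = 13.18  # GHz, longitudinal peak with q parallel to the fiber axis
print(f"f = {f_axial} GHz at q_par  ->  c = {velocity_from_shift(f_axial, q_par):.0f} m/s "
      "(axial longitudinal sound velocity)")
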