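# Koshihikari-like parameter set for the rice growth simulator.
#
# Provenance: representative values for a japonica cultivar assembled from
# the SIMRIW literature (Horie & Nakagawa's model family) and standard rice
# physiology; the cool-damage response (gamma0, Kq, aq) converts the
# published percent-scale form gammaL = 4.6 + 0.054 * Qt^1.56 to fractions.
# The canopy surrogate block (LAI_*, k_beer) parameterizes this package's
# documented developmental LAI curve, not an original SIMRIW component.
# Values are plausible, not a field calibration.

# --- phenology (developmental rate) ---
Gv: 57.0            # d, minimum days to heading at optimal temperature
A: 0.25             # 1/degC, temperature response slope
Th: 17.9            # degC, temperature of half-maximal DVR
DVI_star: 0.46      # DVI at onset of photoperiod sensitivity
Lc: 16.0            # h, critical day length
Bp: 0.85            # 1/h, photoperiod response constant
Gr: 30.5            # d, minimum grain-filling duration
Kr: 0.178           # 1/degC, grain-filling temperature response
Tcr: 12.0           # degC, base temperature of grain filling

# --- dry matter production ---
C0: 1.45            # g DM / MJ absorbed short-wave radiation at 330 ppm CO2
Rm: 0.5             # CO2 response asymptote (dimensionless)
Kc: 330.0           # ppm, CO2 response half-saturation offset
Cf: 1.45            # g DM / MJ, grain-filling efficiency scale (= C0 for continuity)
Bf: 0.001           # grain-filling decline shape
tf: 0.1             # grain-filling decline time constant (DVI units)

# --- yield formation ---
hm: 0.40            # maximum harvest index
Kh: 5.5             # harvest-index development constant
gamma0: 0.046       # baseline spikelet sterility fraction
Kq: 0.00054         # cool-damage response coefficient (fraction per (degC d)^aq)
aq: 1.56            # cool-damage response exponent

# --- canopy surrogate ---
LAI_max: 5.0        # m2/m2, peak leaf area index at heading (DVI = 1)
k_beer: 0.6         # Beer-law light extinction coefficient
lai_rise_exp: 2.0   # LAI rise shape for DVI in [0, 1]
lai_decline_rate: 1.2   # exponential LAI decline rate after heading
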