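"""Physical constants and default analysis parameters.

Defaults gather every threshold the diagnostics use in one place so that the
configuration layer can assert them and the CLI can override them.
"""

# --- Earth / physics ---
EARTH_RADIUS_M = 6_371_000.0
EARTH_OMEGA = 7.2921e-5  # rad/s, Earth's rotation rate
GRAVITY = 9.81  # m/s^2

# --- Seawater (linear equation of state; see docs/methods.md) ---
RHO_SEAWATER = 1025.0  # kg/m^3 reference density
CP_SEAWATER = 3985.0  # J/(kg K)
EOS_ALPHA = 2.0e-4  # 1/K thermal expansion
EOS_BETA = 7.6e-4  # 1/psu haline contraction
EOS_T0 = 10.0  # degC reference
EOS_S0 = 35.0  # psu reference

# --- Air ---
RHO_AIR = 1.15  # kg/m^3
LATENT_HEAT_VAP = 2.5e6  # J/kg

# --- Carbon accounting ---
MOLAR_MASS_C = 12.011  # g/mol
GRAMS_PER_TGC = 1.0e12  # 1 TgC = 10^12 g

# --- TC tracking defaults ---
MSLP_CANDIDATE_THRESHOLD_HPA = 1010.0  # candidate iff MSLP strictly below
CANDIDATE_MASK_RADIUS_KM = 800.0
CANDIDATE_WIND_RADIUS_KM = 200.0  # neighborhood for candidate wind attribution
STITCH_WIND_MIN_MS = 17.0  # tropical-storm-force floor for linking
LINK_RADIUS_KM = 100.0
LINK_WINDOW_H = 24.0
GENESIS_LAT_BAND = (0.0, 35.0)  # absolute latitude, degrees
TRACK_MIN_LIFETIME_H = 24.0  # retained iff strictly greater
TRACK_MIN_LMI_MS = 33.0  # hurricane strength, strictly greater

# --- Saffir-Simpson thresholds (m/s, lower bound of each category) ---
SAFFIR_SIMPSON_MS = {1: 33.0, 2: 43.0, 3: 50.0, 4: 58.0, 5: 70.0}
TROPICAL_STORM_MS = 17.0

# --- Composite diagnostics defaults ---
CIRCLE_RADIUS_KM = 200.0
WAKE_LEAD_H = 24.0  # reference time before passage
WAKE_LAG_H = 24.0  # sampling time after passage
ANOMALY_REF_OFFSET_H = 12.0
CUMFLUX_START_OFFSET_H = -24.0

# --- Mixed-layer depth density thresholds (kg/m^3) ---
MLD_THRESHOLDS = (0.03, 0.125)

# --- pCO2 decomposition ---
GAMMA_SST = 0.0423  # 1/degC, fractional pCO2 change per degree
GAMMA_SSS = 1.0

# --- Export diagnostics ---
EXPORT_LAG_DAYS = 9.0
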