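"""Physical constants and study defaults, collected in one auditable place.

Every tunable the library uses — unit conversions, the empirical correction
factors of the corrected Newtonian method, the hematocrit–viscosity
regression coefficients, the image-segmentation thresholds and the
orientation-class boundaries — lives here so that fidelity-vs-exactness
choices (e.g. the printed rounded coefficient 5.5 versus the exact
8/1.45) are visible and overridable in a single module.
"""

# --- unit conversions (fixed) -------------------------------------------
CP_TO_PA_S = 1e-3          # 1 centipoise = 1e-3 Pa·s
MM_TO_M = 1e-3

# --- corrected Newtonian method -----------------------------------------
#: empirical centreline-to-mean velocity ratio in small arteries
#: (parabolic Newtonian profile would give 2.0)
VMAX_VM_RATIO = 1.45
#: the rounded published coefficient 8/1.45 ≈ 5.5 used by default;
#: pass exact_coefficient=True to use 8/ratio un-rounded
CORRECTED_N_COEFFICIENT = 5.5
#: multiplicative correction turning plasma viscosity into an apparent
#: whole-blood viscosity
APPARENT_VISCOSITY_FACTOR = 1.78

# --- hematocrit -> whole-blood viscosity regression ---------------------
# eta_b [Pa·s] = slope * Ht + intercept, Ht as a fraction in (0, 1)
REGRESSION_SLOPE_PA_S = 0.01258
REGRESSION_INTERCEPT_PA_S = -0.001443

# --- pooled group plasma viscosities [cP] -------------------------------
ETA_P_MALE_CP = 1.26
ETA_P_FEMALE_CP = 1.27
#: sex-pooled plasma viscosity used by the method-comparison sweeps
ETA_P_POOLED_CP = 1.265

# --- image pipeline ------------------------------------------------------
#: background-threshold multiplier; one-sided Gaussian tail at 3.89 leaves
#: 0.005% of background voxels above threshold (99.995% retained)
BACKGROUND_K = 3.89
#: minimum object areas [µm²] for size segmentation
NUCLEUS_MIN_AREA_UM2 = 10.0
GOLGI_MIN_AREA_UM2 = 2.0
#: pixel size of the acquisition geometry [µm] (78 nm)
PIXEL_SIZE_UM = 0.078

# --- orientation classes (degrees on the [0, 180] semicircle) ------------
# dromic [0, 60) | lateral [60, 120) | antidromic [120, 180]
DROMIC_MAX_DEG = 60.0
LATERAL_MAX_DEG = 120.0
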