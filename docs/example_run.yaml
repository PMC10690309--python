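# Annotated pipeline configuration for `renoct run all --config ... --seed N`.
# A run is fully determined by this file plus the root seed.

# --- phantom generation ---------------------------------------------------
n_subjects: 5                # simulated kidneys; the unit of cross-testing
n_per_class_per_subject: 20  # B-scans rendered per tissue class per subject
subject_jitter: 0.15         # per-subject relative jitter of mu and i0
noise_floor: 0.0             # additive mean background; 0 keeps pelvis pixels
                             # at zero so the class abstains as observed
speckle_looks: 1.0           # 1 = fully developed (exponential) speckle;
                             # >1 = gamma speckle of that many looks

# Override individual phenotype parameters (see renoct.phantom defaults).
phenotype_overrides: {}
# phenotype_overrides:
#   tumor: {mu: 9.0}         # e.g. a more strongly attenuating tumor

# --- attenuation estimation ----------------------------------------------
roi_width_px: 200            # lateral extent of the fitting region
roi_depth_px: 250            # depth window of the log-slope fit
roi_depth_offset_px: 10      # window start below the detected lens surface

# --- outputs ---------------------------------------------------------------
save_images: false           # also write one 16-bit TIFF per scan
log_level: INFO
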