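# Annotated experiment configuration for `aieclust simulate-experiment`.
# Every key is validated; unknown keys are rejected with their section path.
# All values shown are the package defaults.

cell_model: clustered        # "clustered" (high-expression-like, Thomas process)
                             # or "dispersed" (low-expression-like, CSR)

footprint:                   # star-shaped polygonal cell outline
  mean_radius_nm: 5000.0     # ~10 um cell diameter
  irregularity: 0.25         # radial perturbation amplitude, must be < 1
  n_vertices: 48

cluster:                     # Thomas-process parameters (clustered model)
  parent_intensity: 0.4      # cluster centres per um^2
  mean_offspring: 25.0       # mean receptors per cluster (Poisson)
  cluster_sd: 30.0           # Gaussian offspring scatter, nm
  hardcore: 2.0              # minimum pairwise separation, nm

csr_intensity_per_um2: 15.0  # receptor density of the dispersed model

disruption:                  # p(D,t) = p_max * (1 - exp(-t/tau)) * D^n/(D^n + ec50^n)
  p_max: 0.8                 # saturating relocation probability
  ec50: 1.0                  # ug/mL
  hill: 1.0                  # Hill exponent n
  time_scale: 8.0            # tau, h

aie:                         # proximity-gated dye
  d_min: 2.13                # turn-on window lower edge, nm
  d_max: 6.62                # turn-on window upper edge, nm
  unit_brightness: 500.0     # photons per emissive fluorophore per exposure

conventional_brightness: 500.0  # photons per labelled fluorophore (control dye)
labeling_efficiency: 0.9        # probability a receptor carries a dye

optics:
  pixel_size: 325.0          # nm/px (20x objective, 6.5 um camera pixel)
  psf_sigma: 170.0           # Gaussian PSF sd, nm
  background: 10.0           # photons/px
  read_noise_sd: 3.0         # photons
  image_shape: [72, 72]      # rows, cols

segmentation:                # plate-analysis settings; see docs/methods.md §4
  smooth_sigma: 8.0          # px; above the cluster spacing on purpose
  gradient_threshold_method: fixed   # "otsu" or "fixed"
  fixed_threshold: 10.0      # gradient units; calibrated to the optics above
  closing_radius: 2          # px
  min_object_area: 100       # px

doses: [0.0, 0.01, 0.1, 1.0, 10.0, 100.0]  # ug/mL, serial dilution
times: [2.0, 8.0, 24.0]                    # h
replicates: 3                              # wells per condition
cells_per_well: 25                         # imaged cells pooled per well
master_seed: 0                             # seeds every random stream
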