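{
  "schema_version": 1,
  "levels": 256,
  "description": "Statistical texture presets emulating the nine trained CT attenuation-pattern classes. Emulation is by moments, spatial correlation and concentric banding, not CT physics.",
  "window_sizes": {
    "white": [55, 59],
    "gray": [53, 53],
    "water_halo": [42, 46],
    "fat_halo": [59, 54],
    "black": [53, 56],
    "ischemia": [50, 55],
    "benign_gray": [45, 48],
    "benign_control_like": [44, 66],
    "control": [51, 55]
  },
  "classes": {
    "white": {
      "mean_level": 215, "variance": 120, "skew_direction": -1,
      "correlation_length": 1.5, "roughness": 0.2, "halo_layers": 0
    },
    "gray": {
      "mean_level": 140, "variance": 90, "skew_direction": 0,
      "correlation_length": 1.5, "roughness": 0.4, "halo_layers": 0
    },
    "water_halo": {
      "mean_level": 130, "variance": 250, "skew_direction": 0,
      "correlation_length": 1.0, "roughness": 0.3,
      "halo_layers": 3, "halo_band_levels": [160, 70, 160]
    },
    "fat_halo": {
      "mean_level": 150, "variance": 180, "skew_direction": 0,
      "correlation_length": 1.0, "roughness": 0.3,
      "halo_layers": 3, "halo_band_levels": [170, 110, 170]
    },
    "black": {
      "mean_level": 35, "variance": 60, "skew_direction": 1,
      "correlation_length": 1.0, "roughness": 0.5, "halo_layers": 0
    },
    "ischemia": {
      "mean_level": 55, "variance": 220, "skew_direction": 1,
      "correlation_length": 2.5, "roughness": 0.6, "halo_layers": 0
    },
    "benign_gray": {
      "mean_level": 150, "variance": 70, "skew_direction": 0,
      "correlation_length": 2.0, "roughness": 0.35, "halo_layers": 0
    },
    "benign_control_like": {
      "mean_level": 175, "variance": 100, "skew_direction": 0,
      "correlation_length": 1.8, "roughness": 0.3, "halo_layers": 0
    },
    "control": {
      "mean_level": 170, "variance": 110, "skew_direction": 0,
      "correlation_length": 1.2, "roughness": 0.45, "halo_layers": 0
    }
  },
  "background": {
    "mean_level": 128, "variance": 3000, "skew_direction": 0,
    "correlation_length": 0.0, "roughness": 1.0, "halo_layers": 0
  }
}
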