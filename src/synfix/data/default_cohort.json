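{
  "n_ankles": 100,
  "seed": 42,
  "artery_along_mm": 4.0,
  "levels": [
    {
      "level_cm": 0.5,
      "angle_mean_deg": 29.42,
      "angle_sd_deg": 6.61,
      "artery_mean_offset_mm": 7.3,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 2.5
    },
    {
      "level_cm": 1.0,
      "angle_mean_deg": 31.12,
      "angle_sd_deg": 6.72,
      "artery_mean_offset_mm": 7.3,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 2.5
    },
    {
      "level_cm": 1.5,
      "angle_mean_deg": 32.99,
      "angle_sd_deg": 6.84,
      "artery_mean_offset_mm": 3.461053012536439,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 0.1
    },
    {
      "level_cm": 2.0,
      "angle_mean_deg": 34.48,
      "angle_sd_deg": 6.37,
      "artery_mean_offset_mm": 2.1528834166186073,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 0.1
    },
    {
      "level_cm": 2.5,
      "angle_mean_deg": 35.91,
      "angle_sd_deg": 6.32,
      "artery_mean_offset_mm": 1.7912573063010484,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 0.1
    },
    {
      "level_cm": 3.0,
      "angle_mean_deg": 36.93,
      "angle_sd_deg": 6.42,
      "artery_mean_offset_mm": 1.8000845418664824,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 0.1
    },
    {
      "level_cm": 3.5,
      "angle_mean_deg": 38.45,
      "angle_sd_deg": 6.67,
      "artery_mean_offset_mm": 1.704120625071397,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 0.1
    },
    {
      "level_cm": 4.0,
      "angle_mean_deg": 39.49,
      "angle_sd_deg": 7.0,
      "artery_mean_offset_mm": 1.907096160522741,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 0.1
    },
    {
      "level_cm": 4.5,
      "angle_mean_deg": 40.79,
      "angle_sd_deg": 7.07,
      "artery_mean_offset_mm": 1.9327656281451766,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 0.1
    },
    {
      "level_cm": 5.0,
      "angle_mean_deg": 41.97,
      "angle_sd_deg": 7.25,
      "artery_mean_offset_mm": 1.801123319990694,
      "artery_sd_mm": 1.2,
      "min_clearance_mm": 0.1
    }
  ]
}
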