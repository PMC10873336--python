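# Sunflower (Helianthus annuus) requirement ranges, after the FAO ECOCROP
# database defaults for rain-fed production.
crop: sunflower
climate:
  rain_season_mm: [300, 1600]   # seasonal rainfall total
  temp_c: [17, 34]              # optimal mean temperature
  cycle_days: [90, 160]         # growth-cycle duration
terrain:
  slope_max_percent: 8.3
  elevation_max_m: 2600
  elevation_well_suited_m: 1500
soil:
  ph: [6.0, 7.5]
  salinity_max_ds_m: 4.0
  bulk_density_g_cm3: 1.4
  soil_water_content_percent: 16.0
  soil_depth_cm: [50, 150]
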