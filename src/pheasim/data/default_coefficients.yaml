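# Default coefficient configuration for the habitat suitability equation.
#
# The intercept (3.07, log scale) is the published value.  The slope
# values below are PLACEHOLDERS: the fitted slopes of the source
# regression are not published alongside the intercept, so these were
# chosen only to have field-plausible signs and shapes (trees negative;
# CRP, rangeland, wetland positive; row crop and small grain hump-shaped
# cubics peaking at intermediate cover).  Replace them with fitted
# coefficients before drawing any substantive conclusion.
intercept: 3.07
slopes:
  rangeland: 0.8
  crp: 1.5
  row_crop: 4.0
  row_crop_sq: -6.0
  row_crop_cu: 1.5
  small_grain: 3.0
  small_grain_sq: -4.5
  small_grain_cu: 1.0
  trees: -2.5
  wetland: 1.2
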