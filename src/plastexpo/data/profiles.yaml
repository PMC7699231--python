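# Default Monte Carlo age-group profiles.
#
# PLACEHOLDER VALUES, NOT AUTHORITATIVE.  The anthropometric and
# activity statistics a real assessment needs come from a national
# exposure-factors handbook; the numbers below are plausible values for
# Korean children chosen so the engine is exercisable and testable.
# Supply your own profile file for any real assessment.
#
# Units: BW kg; SA cm2 (hand skin, the only dermal contact surface);
# CA cm2 (mouthing contact area); D_mouthing min/h; ED h/d (daily
# duration of the activity mapped to each product category:
# stay-in-home -> accessories, stay-out-of-home -> shoes,
# playing -> mat & toy, study -> stationery,
# personal sanitation -> toilet).
#
# Anthropometric draws are truncated normals (bounds default to
# mean +/- 3 SD and 0).
age_groups:
  "0-2":
    BW: {kind: truncated_normal, mean: 11.0, sd: 2.0}
    SA: {kind: truncated_normal, mean: 300.0, sd: 40.0}
    CA: {kind: truncated_normal, mean: 10.0, sd: 2.0}
    D_mouthing: {kind: truncated_normal, mean: 8.0, sd: 3.0}
    ED:
      accessories: {kind: truncated_normal, mean: 16.0, sd: 3.0}
      shoes: {kind: truncated_normal, mean: 2.0, sd: 1.0}
      mat: {kind: truncated_normal, mean: 3.0, sd: 1.0}
      toy: {kind: truncated_normal, mean: 3.0, sd: 1.0}
      stationery: {kind: truncated_normal, mean: 0.5, sd: 0.3}
      toilet: {kind: truncated_normal, mean: 0.5, sd: 0.2}
  "3-12":
    BW: {kind: truncated_normal, mean: 25.0, sd: 6.0}
    SA: {kind: truncated_normal, mean: 450.0, sd: 60.0}
    CA: {kind: truncated_normal, mean: 10.0, sd: 2.0}
    D_mouthing: {kind: truncated_normal, mean: 0.8, sd: 0.4}
    ED:
      accessories: {kind: truncated_normal, mean: 14.0, sd: 2.0}
      shoes: {kind: truncated_normal, mean: 4.0, sd: 1.5}
      mat: {kind: truncated_normal, mean: 2.0, sd: 1.0}
      toy: {kind: truncated_normal, mean: 2.0, sd: 1.0}
      stationery: {kind: truncated_normal, mean: 3.0, sd: 1.0}
      toilet: {kind: truncated_normal, mean: 0.5, sd: 0.2}
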