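{
  "space": ["tpsa", "wlogp"],
  "white": {"center": [71.051, 2.292], "width": 142.081, "height": 8.740, "angle_deg": -1.031325},
  "yolk": {"center": [38.117, 3.481], "width": 82.061, "height": 5.557, "angle_deg": -0.171887},
  "note": "Published two-ellipse absorption model: white = passive GI absorption (HIA), yolk = blood-brain-barrier penetration (BBB); yolk wins overlaps."
}
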