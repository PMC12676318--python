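{
  "note": "Coarse polygonal phi/psi regions (degrees): alpha, beta and left-handed-alpha basins. Favored polygons sit inside the corresponding allowed polygons.",
  "favored": [
    [[-100, -80], [-100, -5], [-30, -5], [-30, -80]],
    [[-170, 90], [-170, 180], [-50, 180], [-50, 90]],
    [[40, -10], [40, 80], [90, 80], [90, -10]]
  ],
  "allowed": [
    [[-180, -120], [-180, 30], [-20, 30], [-20, -120]],
    [[-180, 70], [-180, 180], [-40, 180], [-40, 70]],
    [[-180, -180], [-180, -150], [-40, -150], [-40, -180]],
    [[20, -30], [20, 100], [110, 100], [110, -30]]
  ]
}
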