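{
  "version": "1.0",
  "comment": "Coarse polygonal Ramachandran Favored/Allowed boundaries per residue class, on the phi/psi torus in degrees. Swappable package data: replace with finer contours without code changes. Allowed polygons need not contain the favored ones; classification tests favored first.",
  "classes": {
    "General": {
      "favored": [
        [[-140, -65], [-140, -10], [-45, -10], [-45, -65]],
        [[-170, 100], [-170, 175], [-50, 175], [-50, 100]]
      ],
      "allowed": [
        [[-180, -90], [-180, 30], [-30, 30], [-30, -90]],
        [[-180, 60], [-180, 180], [-30, 180], [-30, 60]],
        [[-180, -180], [-180, -150], [-30, -150], [-30, -180]],
        [[30, -10], [30, 80], [90, 80], [90, -10]]
      ]
    },
    "Gly": {
      "favored": [
        [[-140, -65], [-140, -10], [-45, -10], [-45, -65]],
        [[45, 10], [45, 65], [140, 65], [140, 10]],
        [[-180, 100], [-180, 180], [-50, 180], [-50, 100]],
        [[50, -180], [50, -100], [180, -100], [180, -180]]
      ],
      "allowed": [
        [[-180, -90], [-180, 180], [-30, 180], [-30, -90]],
        [[30, -180], [30, 90], [180, 90], [180, -180]],
        [[-180, -180], [-180, -150], [-30, -150], [-30, -180]],
        [[30, 150], [30, 180], [180, 180], [180, 150]]
      ]
    },
    "Pro": {
      "favored": [
        [[-90, -60], [-90, -10], [-50, -10], [-50, -60]],
        [[-90, 110], [-90, 180], [-50, 180], [-50, 110]]
      ],
      "allowed": [
        [[-110, -75], [-110, 30], [-40, 30], [-40, -75]],
        [[-110, 60], [-110, 180], [-40, 180], [-40, 60]],
        [[-110, -180], [-110, -150], [-40, -150], [-40, -180]]
      ]
    },
    "PrePro": {
      "favored": [
        [[-140, -65], [-140, -10], [-45, -10], [-45, -65]],
        [[-170, 100], [-170, 175], [-50, 175], [-50, 100]]
      ],
      "allowed": [
        [[-180, -90], [-180, 30], [-30, 30], [-30, -90]],
        [[-180, 60], [-180, 180], [-30, 180], [-30, 60]],
        [[-180, -180], [-180, -150], [-30, -150], [-30, -180]],
        [[30, -10], [30, 80], [90, 80], [90, -10]]
      ]
    }
  }
}
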