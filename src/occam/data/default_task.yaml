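# Versioned default task geometry.
#
# Coordinates are abstract data-plane units, y increasing upward; each
# variant's shapes sit at y = +/-1 and are mirrored across the x-axis when a
# trial swaps which shape is on top. The per-variant sigma values were frozen
# by calibrate_difficulty (target: ideal-Bayes minus maximum-likelihood
# generative accuracy gap of 1 percentage point, the level at which complexity
# penalties matter but do not dominate). n_obs is the number of points shown
# per trial.
#
# Arc convention: angle0/span in radians measured at the arc center;
# orientation +1 sweeps counterclockwise. The robustness arc has the same arc
# length (Jeffreys volume) as its paired segment and opens toward it, so its
# center of curvature lies on the opposing model's side (positive curvature
# sign under the package convention).
version: 1
variants:
  - name: dimensionality
    sigma: 3.2369
    n_obs: 10
    mirror_randomization: true
    shape_up: {kind: point, location: [0.0, 1.0], label: simple}
    shape_down: {kind: segment, a: [-1.0, -1.0], b: [1.0, -1.0], label: complex}
  - name: boundary
    sigma: 3.1769
    n_obs: 10
    mirror_randomization: true
    shape_up: {kind: segment, a: [-2.0, 1.0], b: [0.0, 1.0], label: left}
    shape_down: {kind: segment, a: [0.0, -1.0], b: [2.0, -1.0], label: right}
  - name: volume
    sigma: 2.6848
    n_obs: 10
    mirror_randomization: true
    shape_up: {kind: segment, a: [-0.25, 1.0], b: [0.25, 1.0], label: simple}
    shape_down: {kind: segment, a: [-3.0, -1.0], b: [3.0, -1.0], label: complex}
  - name: robustness
    sigma: 0.8391
    n_obs: 10
    mirror_randomization: true
    shape_up: {kind: segment, a: [-1.5, 0.75], b: [1.5, 0.75], label: straight}
    shape_down:
      # three-quarter circle of arc length 3 (radius 3/(1.5*pi)), opening
      # toward the segment; its center of curvature lies on the opposing
      # model's side (positive curvature sign under the package convention)
      kind: arc
      center: [0.0, -0.11338022763241873]   # -0.75 + 2/pi
      radius: 0.6366197723675814
      angle0: -3.9269908169872414           # -1.25*pi
      span: 4.71238898038469                # 1.5*pi, arc length 3
      orientation: 1
      label: curved
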