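"""Real solid-harmonic expansion coefficients over raw Cartesian monomials.

S_lm = sum_c C2S[l][m+l][c] * x**lx * y**ly * z**lz with Racah normalization
(S_00 = 1, S_11 = x, S_20 = z**2 - (x**2+y**2)/2, ...). Monomial order is
lx-major descending, matching the Cartesian component order of the integral
kernels. Generated numerically once and frozen.
"""

C2S = {
    0: [[1.0]],
    1: [[0.0, 1.0000000000000009, 0.0], [0.0, 0.0, 1.0000000000000004], [1.0, 0.0, 0.0]],
    2: [[0.0, 1.732050807568877, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 1.7320508075688763, 0.0], [-0.5, 0.0, 0.0, -0.5000000000000001, 0.0, 0.9999999999999998], [0.0, 0.0, 1.7320508075688776, 0.0, 0.0, 0.0], [0.8660254037844387, 0.0, 0.0, -0.8660254037844382, 0.0, 0.0]],
    3: [[0.0, 2.3717082451262845, 0.0, 0.0, 0.0, 0.0, -0.7905694150420948, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0, 3.872983346207418, 0.0, 0.0, 0.0, 0.0, 0.0], [0.0, -0.6123724356957944, 0.0, 0.0, 0.0, 0.0, -0.6123724356957948, 0.0, 2.449489742783178, 0.0], [0.0, 0.0, -1.4999999999999998, 0.0, 0.0, 0.0, 0.0, -1.5000000000000002, 0.0, 0.9999999999999998], [-0.6123724356957942, 0.0, 0.0, -0.612372435695796, 0.0, 2.4494897427831797, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.9364916731037107, 0.0, 0.0, 0.0, 0.0, -1.9364916731037067, 0.0, 0.0], [0.7905694150420937, 0.0, 0.0, -2.371708245126284, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]],
}
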