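"""Independent brute-force oracles used only by the tests.

These re-derive expected values by direct per-voxel / per-code evaluation,
deliberately sharing no code with the vectorized implementation.
"""

import numpy as np

SQUARE = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]


def bilinear_at(plane_img, a, b):
    """Scalar bilinear interpolation at fractional coordinates (a, b)."""
    ia, ib = int(np.floor(a)), int(np.floor(b))
    fa, fb = a - ia, b - ib
    top = (1 - fb) * plane_img[ia, ib] + fb * plane_img[ia, ib + 1]
    bot = (1 - fb) * plane_img[ia + 1, ib] + fb * plane_img[ia + 1, ib + 1]
    return (1 - fa) * top + fa * bot


def lbp_code_at(data, center, plane_axes, P=8, R_vox=1.0, sampling="circular_interpolated"):
    """Direct evaluation of one voxel's LBP code on one plane."""
    ax_a, ax_b = plane_axes
    other = ({0, 1, 2} - {ax_a, ax_b}).pop()
    idx = [0, 0, 0]
    idx[other] = center[other]
    sl = [slice(None)] * 3
    sl[other] = center[other]
    img = data[tuple(sl)]
    # data[tuple(sl)] drops the fixed axis; remaining axes keep their order
    ca, cb = (center[ax_a], center[ax_b]) if ax_a < ax_b else (center[ax_b], center[ax_a])
    if ax_a > ax_b:
        img = img.T
        ca, cb = center[ax_a], center[ax_b]
    vc = img[ca, cb]
    code = 0
    for p in range(P):
        if sampling == "square":
            da, db = SQUARE[p]
            da, db = da * int(round(R_vox)), db * int(round(R_vox))
            vp = img[ca + da, cb + db]
        else:
            theta = 2 * np.pi * p / P
            da, db = R_vox * np.cos(theta), R_vox * np.sin(theta)
            if abs(da - round(da)) < 1e-9:
                da = round(da)
            if abs(db - round(db)) < 1e-9:
                db = round(db)
            a, b = ca + da, cb + db
            if float(a).is_integer() and float(b).is_integer():
                vp = img[int(a), int(b)]
            else:
                vp = bilinear_at(img, a, b)
        if vp >= vc:
            code |= 1 << p
    return code


def uniformity_oracle(code, P):
    """Circular transition count via explicit bit-string rotation."""
    bits = format(code, f"0{P}b")
    rotated = bits[1:] + bits[0]
    return sum(x != y for x, y in zip(bits, rotated))


def nearest_neighbor_oracle(train_X, train_y, test_X):
    """Exhaustive 1-NN with explicit first-minimum tie rule."""
    preds = []
    for t in np.atleast_2d(test_X):
        best, best_d = None, np.inf
        for i, row in enumerate(np.atleast_2d(train_X)):
            d = float(np.sqrt(np.sum((t - row) ** 2)))
            if d < best_d:  # strict: ties keep the earlier index
                best, best_d = i, d
        preds.append(train_y[best])
    return np.asarray(preds)
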