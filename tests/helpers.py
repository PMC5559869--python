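"""Independent oracles used by the test suite.

These are deliberately written as slow, exhaustive, pure-Python
computations so they share no code path with the vectorized
implementations they check.
"""

import math


def mirror_overlap_oracle(mask, spacing, origin, axis_angle_deg, reference=(0.0, 1.0)):
    """Exhaustive per-pixel reflection-counting symmetry ratio.

    Loops over every foreground pixel, reflects its centre about the
    axis through the foreground centroid at ``axis_angle_deg`` clockwise
    from ``reference``, and accumulates hand-computed bilinear membership
    weights of the reflected point.
    """
    h, w = mask.shape
    n = 0
    sx = sy = 0.0
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                n += 1
                sx += origin[0] + j * spacing
                sy += origin[1] + i * spacing
    if n == 0:
        raise ValueError("empty mask")
    cx, cy = sx / n, sy / n
    rx, ry = reference
    nr = math.hypot(rx, ry)
    rx, ry = rx / nr, ry / nr
    a = math.radians(axis_angle_deg)
    ux = math.cos(a) * rx + math.sin(a) * ry
    uy = -math.sin(a) * rx + math.cos(a) * ry
    total = 0.0
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            px = origin[0] + j * spacing - cx
            py = origin[1] + i * spacing - cy
            d = px * ux + py * uy
            qx = 2.0 * d * ux - px
            qy = 2.0 * d * uy - py
            gc = (qx + cx - origin[0]) / spacing
            gr = (qy + cy - origin[1]) / spacing
            c0 = math.floor(gc)
            r0 = math.floor(gr)
            fc = gc - c0
            fr = gr - r0
            for dr, wr in ((0, 1.0 - fr), (1, fr)):
                for dc, wc in ((0, 1.0 - fc), (1, fc)):
                    rr, cc = r0 + dr, c0 + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        total += wr * wc
    return total / n


def shoelace_area(vertices):
    """Closed-polygon area by the shoelace formula (plain Python)."""
    n = len(vertices)
    acc = 0.0
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        acc += x1 * y2 - x2 * y1
    return abs(acc) / 2.0


def circular_diff_oracle(a, b):
    """Minimal signed a-b on the 180-degree circle by brute enumeration."""
    candidates = [a - b + k * 180.0 for k in (-2, -1, 0, 1, 2)]
    best = min(candidates, key=abs)
    if best == -90.0:
        best = 90.0
    return best
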