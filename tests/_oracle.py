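"""Independent per-voxel scalar reference for the zonal loss, written as a
plain Python loop over voxels (no shared code with the vectorized path)."""

import math


def scalar_zonal_loss(p, m, gamma, eps=1e-7):
    total = 0.0
    flat_p = p.reshape(2, -1)
    flat_m = m.reshape(2, -1)
    for v in range(flat_p.shape[1]):
        p0, p1 = float(flat_p[0, v]), float(flat_p[1, v])
        m0, m1 = int(flat_m[0, v]), int(flat_m[1, v])
        q0 = p0 if m0 == 1 else max(p0, p1)
        q1 = min(p0, p1) if m1 == 1 else p1
        for q, lab in ((q0, m0), (q1, m1)):
            q = min(max(q, eps), 1.0 - eps)
            if lab:
                total += (1.0 - q) ** gamma * -math.log(q)
            else:
                total += q ** gamma * -math.log(1.0 - q)
    return total
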