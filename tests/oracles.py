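"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own arithmetic paths: rectangle
overlap comes from shapely, disk means from an explicit double loop, and
greedy suppression from a literal restatement of the rule.
"""

import numpy as np
from shapely.geometry import box as shapely_box

from beadquant import BeadBox


def shapely_iou(a: BeadBox, b: BeadBox) -> float:
    ra = shapely_box(a.x, a.y, a.x + a.w, a.y + a.h)
    rb = shapely_box(b.x, b.y, b.x + b.w, b.y + b.h)
    inter = ra.intersection(rb).area
    return inter / (ra.area + rb.area - inter) if inter > 0 else 0.0


def brute_force_nms(boxes, threshold):
    """Greedy rule verbatim: keep the max-confidence box (ties by y then x),
    delete everything overlapping it beyond the threshold, repeat."""
    pool = list(boxes)
    kept = []
    while pool:
        best = pool[0]
        for b in pool[1:]:
            if (b.confidence, -b.y, -b.x) > (best.confidence, -best.y, -best.x):
                best = b
        kept.append(best)
        pool = [b for b in pool if b is not best and shapely_iou(best, b) <= threshold]
    return kept


def brute_force_disk_mean(img, cx, cy, r):
    """Exhaustive per-pixel disk mean with the pixel-center inclusion rule."""
    total, n = 0.0, 0
    h, w = img.shape
    for iy in range(h):
        for ix in range(w):
            if (ix - cx) ** 2 + (iy - cy) ** 2 <= r * r:
                total += float(img[iy, ix])
                n += 1
    return total / n, n


def random_boxes(rng, n, image_size=100.0):
    return [
        BeadBox(
            x=rng.uniform(0, image_size - 20),
            y=rng.uniform(0, image_size - 20),
            w=rng.uniform(5, 20),
            h=rng.uniform(5, 20),
            confidence=round(rng.uniform(0.1, 1.0), 3),
        )
        for _ in range(n)
    ]
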