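"""Brute-force oracles (scalar loops / BFS), deliberately independent of
the library implementations they are used to check."""

import numpy as np


def oracle_cnr(image, signal, background):
    """Scalar-loop CNR with population standard deviations."""
    s = [float(image[i, j]) for i in range(image.shape[0])
         for j in range(image.shape[1]) if signal[i, j]]
    b = [float(image[i, j]) for i in range(image.shape[0])
         for j in range(image.shape[1]) if background[i, j]]
    mu_s, mu_b = sum(s) / len(s), sum(b) / len(b)
    var_s = sum((v - mu_s) ** 2 for v in s) / len(s)
    var_b = sum((v - mu_b) ** 2 for v in b) / len(b)
    return (mu_s - mu_b) / (var_s + var_b) ** 0.5


def oracle_vd(mask):
    """Scalar-loop white-pixel fraction."""
    return sum(1 for i in range(mask.shape[0]) for j in range(mask.shape[1])
               if mask[i, j]) / mask.size


def oracle_components(mask):
    """8-connected components by BFS; returns component sizes."""
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                queue, size = [(i, j)], 0
                seen[i, j] = True
                while queue:
                    y, x = queue.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] \
                                    and not seen[yy, xx]:
                                seen[yy, xx] = True
                                queue.append((yy, xx))
                sizes.append(size)
    return sizes


def oracle_vc(mask, min_length=5):
    """BFS connected-component continuity ratio."""
    sizes = oracle_components(mask)
    total = sum(sizes)
    return sum(s for s in sizes if s >= min_length) / total
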