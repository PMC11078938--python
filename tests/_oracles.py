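"""Independent brute-force oracles used by the test suite.

Each function re-implements an operation in the most literal way possible
(per-shift loops, full enumeration, O(n^2) scans) so tests can compare the
package's optimised implementations against a second, structurally
different code path.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.measure import perimeter as sk_perimeter


def zncc_loop(reference: np.ndarray, moving: np.ndarray, max_shift: int):
    """Exhaustive per-shift ZNCC loop.

    Returns (dy, dx, score) with the same tie-break contract as the
    implementation: near-ties (1e-9 relative) resolve to smallest |dy|+|dx|,
    then lexicographic (dy, dx).
    """
    h, w = reference.shape
    scores: dict[tuple[int, int], float] = {}
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            r0, r1 = max(0, -dy), h - max(0, dy)
            c0, c1 = max(0, -dx), w - max(0, dx)
            if r0 >= r1 or c0 >= c1:
                continue
            a = reference[r0:r1, c0:c1].astype(float)
            b = moving[r0 + dy : r1 + dy, c0 + dx : c1 + dx].astype(float)
            a = a - a.mean()
            b = b - b.mean()
            den = math.sqrt((a * a).sum() * (b * b).sum())
            if den <= 1e-12:
                continue
            scores[(dy, dx)] = float((a * b).sum() / den)
    best = max(scores.values())
    eps = 1e-9 * max(1.0, abs(best))
    ties = [s for s, v in scores.items() if v >= best - eps]
    dy, dx = min(ties, key=lambda s: (abs(s[0]) + abs(s[1]), s[0], s[1]))
    return dy, dx, scores[(dy, dx)]


def enumerate_nuclei(
    image: np.ndarray,
    min_area: int,
    max_area: int,
    circularity_min: float,
    peak_threshold: float,
    n_levels: int,
) -> list[np.ndarray]:
    """Literal enumeration of every (threshold, component) candidate.

    Thresholds: evenly spaced intensity levels over the nonzero range.
    Components: 8-connected (scipy labelling, a different library path than
    the implementation).  Rules applied verbatim; conflicts removed greedily
    by descending area (ties: peak, then centroid); returns accepted masks
    sorted by centroid.
    """
    img = np.asarray(image, dtype=float)
    vals = img[img > 0]
    if vals.size == 0 or vals.max() <= vals.min():
        return []
    levels = np.unique(np.linspace(vals.min(), vals.max(), n_levels))
    structure = np.ones((3, 3), dtype=int)
    cands = []
    for t in levels:
        lab, n = ndi.label(img >= t, structure=structure)
        for i in range(1, n + 1):
            mask = lab == i
            area = int(mask.sum())
            peak = float(img[mask].max())
            per = sk_perimeter(mask)
            circ = 4 * math.pi * area / per**2 if per > 0 else 1.0
            ys, xs = np.nonzero(mask)
            cands.append(
                {
                    "mask": mask,
                    "area": area,
                    "peak": peak,
                    "circ": circ,
                    "cen": (float(ys.mean()), float(xs.mean())),
                }
            )
    qual = [
        c
        for c in cands
        if min_area <= c["area"] <= max_area
        and c["circ"] >= circularity_min
        and c["peak"] >= peak_threshold
    ]
    qual.sort(key=lambda c: (-c["area"], -c["peak"], c["cen"][0], c["cen"][1]))
    taken = np.zeros(img.shape, dtype=bool)
    accepted = []
    for c in qual:
        if (taken & c["mask"]).any():
            continue
        taken |= c["mask"]
        accepted.append(c)
    accepted.sort(key=lambda c: (c["cen"][0], c["cen"][1]))
    return [c["mask"] for c in accepted]


def spatial_corr_loop(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Double-loop sum_k sum_l v_ik W_kl v_jl for every protein pair."""
    n_cells, n_prot = V.shape
    out = np.zeros((n_prot, n_prot))
    for i in range(n_prot):
        for j in range(n_prot):
            acc = 0.0
            for k in range(n_cells):
                for l in range(n_cells):
                    acc += V[k, i] * W[k, l] * V[l, j]
            out[i, j] = acc
    return out


def silhouette_loop(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """O(n^2) textbook silhouette; singleton clusters score 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    D = cdist(X, X)
    uniq = np.unique(labels)
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = labels[i]
        own_idx = np.where(labels == own)[0]
        if len(own_idx) == 1:
            s[i] = 0.0
            continue
        a = D[i, own_idx[own_idx != i]].mean()
        b = min(
            D[i, labels == other].mean() for other in uniq if other != own
        )
        s[i] = (b - a) / max(a, b)
    return s


def count_occurrences(transcripts: dict[str, str], kmer: str) -> int:
    """Overlapping substring count of a k-mer across all transcripts."""
    total = 0
    for seq in transcripts.values():
        start = 0
        while True:
            idx = seq.find(kmer, start)
            if idx == -1:
                break
            total += 1
            start = idx + 1
    return total


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def conflict_pairs(seqs: list[str], word_size: int) -> set[tuple[int, int]]:
    """All-pairs scan for shared complementary stretches of >= word_size."""
    pairs = set()
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            rc_j = revcomp(seqs[j])
            for s in range(len(seqs[i]) - word_size + 1):
                if seqs[i][s : s + word_size] in rc_j:
                    pairs.add((i, j))
                    break
    return pairs
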