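import numpy as np
import pytest


def match_puncta(pset, gt):
    """Greedy centroid matching of detected puncta to ground truth.

    A punctum matches if its centroid lies within one ground-truth radius of
    an unused true center. Returns the number of true positives.
    """
    used = set()
    tp = 0
    for p in pset.puncta:
        d = np.linalg.norm(gt.centers_um - np.asarray(p.centroid_um), axis=1)
        j = int(np.argmin(d))
        if d[j] <= gt.radii_um[j] and j not in used:
            used.add(j)
            tp += 1
    return tp


def match_onsets(detected_s, true_s, tol_s=2e-3):
    """Number of detected onsets within tol of an unused true onset."""
    used = set()
    tp = 0
    true_s = np.asarray(true_s)
    for o in detected_s:
        if true_s.size == 0:
            break
        d = np.abs(true_s - o)
        j = int(np.argmin(d))
        if d[j] <= tol_s and j not in used:
            used.add(j)
            tp += 1
    return tp


def flood_fill_26(binary):
    """Independent BFS flood-fill labeling oracle (26-connectivity).

    Deliberately naive: a queue-based flood fill over explicit neighbor
    offsets, sharing no code with the labeling under test.
    """
    from collections import deque

    binary = np.asarray(binary).astype(bool)
    nd = binary.ndim
    offsets = [
        off
        for off in np.ndindex(*([3] * nd))
        if any(o != 1 for o in off)
    ]
    offsets = [tuple(o - 1 for o in off) for off in offsets]
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        q = deque([start])
        labels[start] = current
        while q:
            pos = q.popleft()
            for off in offsets:
                nb = tuple(p + o for p, o in zip(pos, off))
                if any(c < 0 or c >= s for c, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not labels[nb]:
                    labels[nb] = current
                    q.append(nb)
    return labels, current


def partitions_equal(labels_a, labels_b):
    """True iff two label grids induce the same partition of foreground."""
    la = np.asarray(labels_a).ravel()
    lb = np.asarray(labels_b).ravel()
    if not np.array_equal(la > 0, lb > 0):
        return False
    fg = la > 0
    pairs = set(zip(la[fg].tolist(), lb[fg].tolist()))
    # bijective relabeling: each label on one side maps to exactly one on the other
    return len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
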