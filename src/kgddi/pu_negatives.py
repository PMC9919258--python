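"""Positive-unlabeled reliable-negative selection.

Unlabeled drug pairs are screened by distance from the positive "cluster
center": concatenate the two drugs' fingerprints (canonical order, 2B dims —
2048 at B = 1024), average over all positive pairs to get the center,
compute every unlabeled pair's Euclidean distance to it, and keep pairs
whose distance strictly exceeds D = n x AED, where AED is the mean of those
distances. Pairs far from the positive mass in chemical-structure space are
unlikely to be unverified positives, hence "reliable" negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurize import FingerprintSet


class PUError(ValueError):
    """Fatal input error in negative selection."""


@dataclass
class ClusterCenter:
    center: np.ndarray  # length 2B, coordinates in [0,1]
    n_positives: int


@dataclass
class NegativeSelection:
    threshold_multiplier: float
    aed: float
    threshold: float  # n * aed
    selected: list  # pair keys with distance strictly > threshold
    distances: dict = field(repr=False)  # pair key -> distance


def _canonical(a, b):
    return (a, b) if a <= b else (b, a)


def pair_fp(a, b, fps: FingerprintSet) -> np.ndarray:
    """Order-invariant pair fingerprint: [fp(min) | fp(max)] by canonical key order."""
    lo, hi = _canonical(a, b)
    return np.concatenate([fps[lo], fps[hi]])


def cluster_center(positives, fps: FingerprintSet) -> ClusterCenter:
    """Coordinate-wise mean of pair_fp over all positive pairs."""
    if len(positives) == 0:
        raise PUError("cluster center requires at least one positive pair")
    mat = np.stack([pair_fp(a, b, fps) for a, b in positives])
    return ClusterCenter(center=mat.mean(axis=0), n_positives=len(positives))


def select_negatives(
    unlabeled, center: ClusterCenter, n: float, fps: FingerprintSet
) -> NegativeSelection:
    """Keep unlabeled pairs with distance-to-center strictly above n x AED."""
    if len(unlabeled) == 0:
        raise PUError("no unlabeled pairs to select from")
    if n <= 0:
        raise PUError("threshold multiplier n must be > 0")
    dists = {
        (a, b): float(np.linalg.norm(pair_fp(a, b, fps) - center.center))
        for a, b in unlabeled
    }
    aed = float(np.mean(list(dists.values())))
    threshold = n * aed
    selected = [pair for pair, d in dists.items() if d > threshold]
    return NegativeSelection(
        threshold_multiplier=n,
        aed=aed,
        threshold=threshold,
        selected=selected,
        distances=dists,
    )


def random_negatives(unlabeled, k: int, rng: np.random.Generator) -> list:
    """Uniform sample of k unlabeled pairs without replacement (the baseline strategy)."""
    if k > len(unlabeled):
        raise PUError(f"requested {k} negatives from only {len(unlabeled)} unlabeled pairs")
    if k < 0:
        raise PUError("k must be >= 0")
    idx = rng.choice(len(unlabeled), size=k, replace=False)
    return [unlabeled[i] for i in idx]


# -- pair-file dialect ---------------------------------------------------------
# `drug_a<TAB>drug_b<TAB>label[<TAB>itype]`, label in {1, 0, ?}

def load_pairs(path):
    """Read a pair TSV into (pair, label, itype) rows; label None means unlabeled."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise PUError(f"{path}: line {lineno}: expected 3 or 4 columns")
            a, b, lab = parts[0], parts[1], parts[2]
            if lab not in {"0", "1", "?"}:
                raise PUError(f"{path}: line {lineno}: label must be 1, 0 or ?")
            itype = parts[3] if len(parts) == 4 else None
            if itype is not None and itype not in {"increase", "decrease"}:
                raise PUError(f"{path}: line {lineno}: itype must be increase or decrease")
            rows.append(((a, b), None if lab == "?" else int(lab), itype))
    if not rows:
        raise PUError(f"{path}: empty pair file")
    return rows


def write_pairs(rows, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), label, itype in rows:
            lab = "?" if label is None else str(int(label))
            cols = [str(a), str(b), lab] + ([itype] if itype else [])
            fh.write("\t".join(cols) + "\n")
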