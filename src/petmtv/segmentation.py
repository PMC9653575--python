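"""Training and deployment of the organ-segmentation network on CT.

The network labels each axial CT slice with five classes: background plus
the four avid target structures (brain, heart, kidneys, bladder). The two
kidneys are one network class — they are indistinguishable by intensity
and texture, only by side — and are split into left/right after inference
by the x-centroid of their connected components. Preprocessing clips the
intensity range and Z-score-standardizes each volume; training minimizes
a cross-entropy + soft-Dice combination with Adam (weight decay 1e-4), a
learning rate of 3e-4 stepped down to 3e-6 from epoch 60 on,
and affine augmentation (rotation, translation, scaling, flipping).
Volumes are split 5:1:4 into train/validation/test by default.

Inference runs slice-wise and restacks the argmax labels into the 3-D
five-organ mask set of the imaging data model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume, ORGAN_LABELS, ORGAN_NAMES, OrganMaskSet
from .errors import GeometryError
from .nn import Adam, ce_dice_loss_and_grad
from .unet import ResidualUNet

__all__ = [
    "AugmentRanges",
    "TrainConfig",
    "TrainHistory",
    "preprocess_ct",
    "dice_coefficient",
    "combined_loss",
    "augment_pair",
    "split_cases",
    "train_segmentation",
    "fine_tune",
    "segment_organs",
    "evaluate_dice",
]

_KIDNEY_LABELS = (ORGAN_LABELS["kidney_left"], ORGAN_LABELS["kidney_right"])

# The network's class space merges the two kidneys (they differ only by
# side, which is resolved geometrically after inference):
# label space: 0 bg, 1 brain, 2 heart, 3 kidney_L, 4 kidney_R, 5 bladder
# class space: 0 bg, 1 brain, 2 heart, 3 kidneys,  4 bladder
_CLASS_OF_LABEL = np.array([0, 1, 2, 3, 3, 4], dtype=np.uint8)
_LABEL_OF_CLASS = np.array(
    [0, 1, 2, ORGAN_LABELS["kidney_left"], ORGAN_LABELS["bladder"]],
    dtype=np.uint8)


# ---------------------------------------------------------------------------
# Preprocessing and metrics
# ---------------------------------------------------------------------------

def preprocess_ct(volume: ImageVolume | np.ndarray, mode: str = "range") -> np.ndarray:
    """Clip CT intensities and Z-score standardize over the whole volume.

    ``mode='range'`` (default) first shifts the volume to nonnegative
    values, then clips to [0.01*max, 0.99*max] of the shifted intensity
    range; ``mode='percentile'`` clips to the 1st/99th intensity
    percentiles instead. Either way the result is standardized to mean 0,
    SD 1; a zero-variance volume maps to all zeros.
    """
    v = np.asarray(volume.values if isinstance(volume, ImageVolume) else volume,
                   dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot preprocess an empty volume")
    vmin = v.min()
    if vmin < 0:
        v = v - vmin
    if mode == "range":
        vmax = v.max()
        v = np.clip(v, 0.01 * vmax, 0.99 * vmax)
    elif mode == "percentile":
        lo, hi = np.percentile(v, [1.0, 99.0])
        v = np.clip(v, lo, hi)
    else:
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    if a.grid != b.grid:
        raise GeometryError("dice_coefficient requires masks on the same grid")
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a.membership & b.membership).sum())
    return 2.0 * inter / (na + nb)


def combined_loss(probs: np.ndarray, targets: np.ndarray, weight: float = 0.5) -> float:
    """``w*CE + (1-w)*(1 - mean soft-Dice over foreground classes)``.

    ``probs`` holds per-pixel class probabilities (N,C,H,W) summing to one
    over the class axis; ``targets`` is (N,H,W) integer labels.
    """
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets)
    if probs.shape[0] != targets.shape[0] or probs.shape[2:] != targets.shape[1:]:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs targets {targets.shape}")
    # reuse the training loss on log-probabilities (softmax(log p) == p)
    total, _, _, _ = ce_dice_loss_and_grad(
        np.log(np.maximum(probs, 1e-12)), targets, weight=weight)
    return float(total)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentRanges:
    """Affine augmentation ranges; all-zero ranges mean no augmentation."""

    rotation_deg: float = 10.0
    translation_mm: float = 8.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_prob: float = 0.5

    @classmethod
    def none(cls) -> "AugmentRanges":
        return cls(0.0, 0.0, (1.0, 1.0), 0.0)


def augment_pair(
    image: np.ndarray,
    labels: np.ndarray,
    ranges: AugmentRanges,
    rng: np.random.Generator | int,
    spacing_mm: tuple[float, float] = (4.0, 4.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one sampled affine transform to an aligned (slice, labels) pair.

    The image is interpolated linearly, the labels nearest-neighbour, with
    the same rotation/translation/scale about the slice centre. A
    horizontal flip mirrors the x axis; since that mirrors anatomy, the
    left/right kidney label values are exchanged so each label keeps
    meaning "the kidney on that side of the image". Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    theta = math.radians(rng.uniform(-ranges.rotation_deg, ranges.rotation_deg)) \
        if ranges.rotation_deg else 0.0
    t_mm = rng.uniform(-ranges.translation_mm, ranges.translation_mm, size=2) \
        if ranges.translation_mm else np.zeros(2)
    scale = rng.uniform(*ranges.scale_range) if ranges.scale_range != (1.0, 1.0) else 1.0
    do_flip = bool(rng.random() < ranges.flip_prob) if ranges.flip_prob else False

    out_img, out_lab = image, labels
    if theta or t_mm.any() or scale != 1.0:
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s], [s, c]]) / scale
        center = (np.array(image.shape) - 1) / 2.0
        t_vox = t_mm / np.asarray(spacing_mm)
        offset = center - rot @ (center + t_vox)
        out_img = ndimage.affine_transform(image, rot, offset=offset, order=1,
                                           mode="nearest")
        out_lab = ndimage.affine_transform(labels, rot, offset=offset, order=0,
                                           mode="constant", cval=0,
                                           output=labels.dtype)
    if do_flip:
        out_img = out_img[::-1, :].copy()
        out_lab = out_lab[::-1, :].copy()
        left, right = _KIDNEY_LABELS
        l_mask = out_lab == left
        out_lab[out_lab == right] = left
        out_lab[l_mask] = right
    return out_img, out_lab


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule for the segmentation network."""

    max_epochs: int = 100
    learning_rate: float = 3e-4
    final_learning_rate: float = 3e-6
    lr_decay_epoch: int = 60  # step the LR down from this epoch on
    weight_decay: float = 1e-4
    loss_weight: float = 0.5  # CE weight; (1-w) on Dice
    batch_size: int = 4
    slices_per_volume: int = 16
    background_slice_fraction: float = 0.25
    crop_size: int | None = 64  # central in-plane crop for training slices
    augment: AugmentRanges = field(default_factory=AugmentRanges)
    split: tuple[int, int, int] = (5, 1, 4)
    val_interval: int = 10
    trainable_scope: str = "all_layers"  # or "final_layer_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.final_learning_rate <= 0:
            raise ValueError("learning rates must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if sum(self.split) <= 0 or any(s < 0 for s in self.split):
            raise ValueError("split ratio entries must be nonnegative with positive sum")
        if self.trainable_scope not in ("all_layers", "final_layer_only"):
            raise ValueError(f"unknown trainable scope {self.trainable_scope!r}")


@dataclass
class TrainHistory:
    """Per-epoch training loss and periodic per-organ validation Dice."""

    epoch_loss: list[float] = field(default_factory=list)
    val_dice: list[tuple[int, dict[str, float]]] = field(default_factory=list)
    test_dice: dict[str, float] | None = None

    @property
    def initial_loss(self) -> float:
        return self.epoch_loss[0]

    @property
    def final_loss(self) -> float:
        return self.epoch_loss[-1]


def split_cases(cases: list, ratio: tuple[int, int, int],
                rng: np.random.Generator) -> tuple[list, list, list]:
    """Shuffle and split cases by the given ratio (train, val, test)."""
    n = len(cases)
    order = rng.permutation(n)
    total = sum(ratio)
    n_train = int(round(n * ratio[0] / total))
    n_val = int(round(n * ratio[1] / total))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    return ([cases[i] for i in idx_train], [cases[i] for i in idx_val],
            [cases[i] for i in idx_test])


def _foreground_slices(labels: np.ndarray) -> np.ndarray:
    return np.flatnonzero(labels.any(axis=(0, 1)))


def _central_crop_slices(shape: tuple[int, int], crop: int) -> tuple[slice, slice]:
    """Fixed central in-plane window (identity when the slice is smaller).

    A fixed window — rather than a random crop — keeps training and
    inference geometry identical slice to slice.
    """
    nx, ny = shape[:2]
    if crop >= nx and crop >= ny:
        return slice(None), slice(None)
    ox = max((nx - crop) // 2, 0)
    oy = max((ny - crop) // 2, 0)
    return slice(ox, min(ox + crop, nx)), slice(oy, min(oy + crop, ny))


class _SlicePool:
    """Preprocessed volumes with class-stratified per-epoch slice sampling.

    Foreground slices are drawn per network class (brain, heart, kidneys,
    bladder) rather than uniformly over organ-bearing slices: the kidneys
    and bladder occupy narrow z-ranges, and uniform sampling leaves them
    so under-represented that their classes may not have emerged by the
    time the learning-rate decay freezes the network.
    """

    def __init__(self, cases: list[tuple[ImageVolume, np.ndarray]]) -> None:
        self.volumes = [preprocess_ct(ct).astype(np.float32) for ct, _ in cases]
        self.labels = [np.asarray(lab) for _, lab in cases]
        self.fg = [_foreground_slices(lab) for lab in self.labels]
        # per-volume, per-network-class z indices where the class appears
        n_classes = int(_CLASS_OF_LABEL.max())
        self.class_slices: list[list[np.ndarray]] = []
        for lab in self.labels:
            cls = _CLASS_OF_LABEL[lab]
            self.class_slices.append([
                np.flatnonzero((cls == c).any(axis=(0, 1)))
                for c in range(1, n_classes + 1)
            ])
        self.spacing = [ct.grid.spacing[:2] for ct, _ in cases]

    def sample_epoch(self, cfg: TrainConfig, rng: np.random.Generator
                     ) -> list[tuple[int, int]]:
        """(volume index, z index) pairs for one epoch."""
        picks: list[tuple[int, int]] = []
        n_bg = int(round(cfg.slices_per_volume * cfg.background_slice_fraction))
        n_fg = cfg.slices_per_volume - n_bg
        for vi, per_class in enumerate(self.class_slices):
            nz = self.labels[vi].shape[2]
            present = [zs for zs in per_class if zs.size]
            if present:
                # round-robin the foreground quota over the classes present
                for i in range(n_fg):
                    zs = present[i % len(present)]
                    picks.append((vi, int(rng.choice(zs))))
            elif self.fg[vi].size:
                picks += [(vi, int(z)) for z in
                          rng.choice(self.fg[vi], size=n_fg,
                                     replace=self.fg[vi].size < n_fg)]
            if n_bg:
                picks += [(vi, int(z)) for z in rng.integers(0, nz, size=n_bg)]
        order = rng.permutation(len(picks))
        return [picks[i] for i in order]

    def batch(self, picks: list[tuple[int, int]], cfg: TrainConfig,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        imgs, labs = [], []
        for vi, z in picks:
            img = self.volumes[vi][:, :, z]
            lab = self.labels[vi][:, :, z]
            img, lab = augment_pair(img, lab, cfg.augment, rng,
                                    spacing_mm=self.spacing[vi])
            if cfg.crop_size:
                sx, sy = _central_crop_slices(img.shape, cfg.crop_size)
                img, lab = img[sx, sy], lab[sx, sy]
            imgs.append(img)
            labs.append(lab)
        x = np.stack(imgs)[:, None, :, :].astype(np.float32)
        t = _CLASS_OF_LABEL[np.stack(labs)].astype(np.int64)
        return x, t


def _train_loop(model: ResidualUNet, cases: list[tuple[ImageVolume, np.ndarray]],
                cfg: TrainConfig,
                val_cases: list[tuple[ImageVolume, np.ndarray]] | None = None
                ) -> TrainHistory:
    if not cases:
        raise ValueError("training requires at least one labeled case")
    rng = np.random.default_rng(cfg.seed)
    pool = _SlicePool(cases)
    params = model.head_params() if cfg.trainable_scope == "final_layer_only" \
        else model.params()
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.learning_rate if epoch < cfg.lr_decay_epoch \
            else cfg.final_learning_rate
        picks = pool.sample_epoch(cfg, rng)
        losses = []
        for start in range(0, len(picks), cfg.batch_size):
            x, t = pool.batch(picks[start:start + cfg.batch_size], cfg, rng)
            opt.zero_grad()
            logits = model.forward(x, train=True)
            loss, _, _, dlogits = ce_dice_loss_and_grad(logits, t, cfg.loss_weight)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.epoch_loss.append(float(np.mean(losses)))
        if val_cases and cfg.val_interval and (epoch + 1) % cfg.val_interval == 0:
            history.val_dice.append((epoch + 1, evaluate_dice(model, val_cases)))
    return history


def train_segmentation(model: ResidualUNet,
                       cases: list[tuple[ImageVolume, np.ndarray]],
                       cfg: TrainConfig,
                       val_cases: list[tuple[ImageVolume, np.ndarray]] | None = None
                       ) -> tuple[ResidualUNet, TrainHistory]:
    """Train the network on labeled (CT volume, organ label map) cases."""
    history = _train_loop(model, cases, cfg, val_cases)
    return model, history


def fine_tune(model: ResidualUNet,
              cases: list[tuple[ImageVolume, np.ndarray]],
              cfg: TrainConfig,
              val_cases: list[tuple[ImageVolume, np.ndarray]] | None = None
              ) -> tuple[ResidualUNet, TrainHistory]:
    """Reset the final classification layer to random weights, then train.

    Which weights are updated is controlled by ``cfg.trainable_scope``
    ({"final_layer_only", "all_layers"}). With ``max_epochs=0`` the model
    is returned in the freshly reset state.
    """
    rng = np.random.default_rng(cfg.seed)
    model.reset_head(rng)
    if cfg.max_epochs == 0:
        return model, TrainHistory()
    history = _train_loop(model, cases, cfg, val_cases)
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _assign_kidney_sides(labels: np.ndarray) -> np.ndarray:
    """Reassign connected components of the kidney class to left/right by x."""
    left, right = _KIDNEY_LABELS
    kid = (labels == left) | (labels == right)
    if not kid.any():
        return labels
    comp, n = ndimage.label(kid, structure=np.ones((3, 3, 3), dtype=bool))
    out = labels.copy()
    xs = np.arange(labels.shape[0], dtype=np.float64)
    centroids, sizes = [], []
    for ci in range(1, n + 1):
        m = comp == ci
        counts = m.sum(axis=(1, 2)).astype(np.float64)
        centroids.append(float((xs * counts).sum() / counts.sum()))
        sizes.append(int(counts.sum()))
    if n == 1:
        thr = (labels.shape[0] - 1) / 2.0
    else:
        big = np.argsort(sizes)[::-1][:2]
        thr = (centroids[big[0]] + centroids[big[1]]) / 2.0
    for ci in range(1, n + 1):
        m = comp == ci
        out[m] = left if centroids[ci - 1] < thr else right
    return out


def _keep_largest_component(labels: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected component of each organ class.

    Slice-wise inference occasionally produces small stray islands of an
    organ class far from the organ; each is an anatomical impossibility
    (one brain, one heart, one bladder, one kidney per side), and a stray
    island left in place would later carve a hole into the MTV analysis
    space. Standard segmentation postprocessing.
    """
    structure = np.ones((3, 3, 3), dtype=bool)
    out = labels.copy()
    for lab in ORGAN_LABELS.values():
        m = labels == lab
        comp, n = ndimage.label(m, structure=structure)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(m, comp, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        out[m & (comp != keep)] = 0
    return out


def segment_organs(model: ResidualUNet, ct: ImageVolume,
                   batch_size: int = 16,
                   crop_size: int | None = 64,
                   keep_largest: bool = True) -> OrganMaskSet:
    """Segment one CT volume into the five organ masks.

    Slices are processed in batches in eval mode on the same fixed central
    in-plane window the network is trained on (everything outside it is
    background); argmax over classes makes the masks pairwise disjoint by
    construction, components of the single kidney class are attributed to
    left/right by x-centroid, and (by default) only the largest connected
    component of each organ is kept.
    """
    vol = preprocess_ct(ct).astype(np.float32)
    nx, ny, nz = vol.shape
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    sx, sy = _central_crop_slices((nx, ny), crop_size) if crop_size \
        else (slice(None), slice(None))
    for start in range(0, nz, batch_size):
        sl = vol[sx, sy, start:start + batch_size]
        x = np.ascontiguousarray(sl.transpose(2, 0, 1))[:, None, :, :]
        cls = model.predict_labels(x).transpose(1, 2, 0)
        labels[sx, sy, start:start + batch_size] = _LABEL_OF_CLASS[cls]
    labels = _assign_kidney_sides(labels)
    if keep_largest:
        labels = _keep_largest_component(labels)
    return OrganMaskSet.from_label_map(ct.grid, labels)


def evaluate_dice(model: ResidualUNet, cases: list[tuple[ImageVolume, np.ndarray]],
                  ) -> dict[str, float]:
    """Mean per-organ Dice of ``segment_organs`` output against truth labels."""
    per_organ: dict[str, list[float]] = {name: [] for name in ORGAN_NAMES}
    for ct, truth_labels in cases:
        pred = segment_organs(model, ct)
        truth = OrganMaskSet.from_label_map(ct.grid, truth_labels)
        for name in ORGAN_NAMES:
            per_organ[name].append(
                dice_coefficient(getattr(pred, name), getattr(truth, name)))
    return {name: float(np.mean(v)) for name, v in per_organ.items()}
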