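"""Patch extraction, focal loss, octahedral augmentation, training and metrics.

Networks are trained on small cubic patches (7^3, or 1^3 for the
single-voxel SO(3) network) whose label is the center voxel's tissue class.
Class imbalance is countered by the focal loss
``-alpha_y (1 - p_y)^gamma log p_y`` with gamma = 2 and
alpha = (0.35, 0.35, 0.15, 0.15) for CSF, subcortical, WM and GM.

Rotation augmentation draws from the 24-element octahedral group (proper
rotations of the cube) so the voxel grid permutes exactly — no spatial
interpolation; the per-voxel spherical signals rotate with the grid and are
re-expressed at the original b-vectors by Watson interpolation from the
rotated gradient scheme.  The rotated test set applies one independent
octahedral rotation per patch, which probes how much a trained network's
accuracy depends on the orientation of unseen data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .networks import BuiltNetwork
from .spherical_signal import (
    SamplingScheme,
    SphericalVolume,
    rotate_scheme,
    watson_weights,
)

__all__ = [
    "PatchDataset",
    "OctahedralGroup",
    "EvalReport",
    "TrainHistory",
    "octahedral_group",
    "rotate_grid_exact",
    "extract_patches",
    "focal_loss",
    "focal_loss_with_grad",
    "octahedral_augment",
    "build_rotated_testset",
    "evaluate",
    "performance_drop_map",
    "train",
    "FOCAL_GAMMA",
    "FOCAL_ALPHA",
]

FOCAL_GAMMA = 2.0
FOCAL_ALPHA = (0.35, 0.35, 0.15, 0.15)  # CSF, subcortical, WM, GM


@dataclass(frozen=True)
class PatchDataset:
    """Cubic patches with center-voxel labels and provenance coordinates."""

    patches: np.ndarray  # (M, P, P, P, N)
    labels: np.ndarray  # (M,) int in 0..3
    coords: np.ndarray  # (M, 3) center voxel indices
    scheme: SamplingScheme
    scan_ids: np.ndarray | None = None  # (M,) grouping for per-scan metrics

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def patch_size(self) -> int:
        return self.patches.shape[1]


@dataclass(frozen=True)
class OctahedralGroup:
    """The 24 proper rotations of the cube (all matrix entries in {-1, 0, 1})."""

    elements: np.ndarray  # (24, 3, 3)


def octahedral_group() -> OctahedralGroup:
    """Generate the 24 cube rotations by closing two 90-degree generators."""
    gx = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=int)
    gz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=int)
    elements = [np.eye(3, dtype=int)]
    frontier = list(elements)
    while frontier:
        new = []
        for E in frontier:
            for G in (gx, gz):
                P = G @ E
                if not any((P == M).all() for M in elements):
                    elements.append(P)
                    new.append(P)
        frontier = new
    if len(elements) != 24:  # pragma: no cover - structural guarantee
        raise RuntimeError("octahedral closure failed")
    return OctahedralGroup(elements=np.array(elements))


def rotate_grid_exact(values: np.ndarray, R: np.ndarray,
                      spatial_axes: tuple[int, int, int] = (0, 1, 2)) -> np.ndarray:
    """Permute a cubic grid by an integer rotation: ``out[x] = in[R^-1 (x-c) + c]``.

    ``R`` must have entries in {-1, 0, 1} and be a proper rotation; the grid
    must be cubic along ``spatial_axes``.  Exact (no interpolation).
    """
    R = np.asarray(R)
    if np.abs(np.round(R) - R).max() > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
        raise ValueError("R must be an integer proper rotation")
    Ri = np.round(np.linalg.inv(R)).astype(int)
    S = values.shape[spatial_axes[0]]
    if any(values.shape[a] != S for a in spatial_axes):
        raise ValueError("grid must be cubic along the spatial axes")
    c = (S - 1) / 2.0
    idx = np.indices((S, S, S)).reshape(3, -1)
    src = (Ri @ (idx - c) + c)
    src = np.round(src).astype(int)
    out = np.moveaxis(values, spatial_axes, (0, 1, 2))
    out = out[src[0], src[1], src[2]].reshape(out.shape)
    return np.moveaxis(out, (0, 1, 2), spatial_axes)


def extract_patches(volume: SphericalVolume, labels: np.ndarray,
                    patch_size: int = 7, stride: int = 1,
                    max_patches: int | None = None, seed: int = 0,
                    balance: bool = False,
                    scan_id: int = 0) -> PatchDataset:
    """Deterministic patch extraction around masked, labeled centers.

    Centers fall on a ``stride`` grid, must lie inside the mask, carry a
    valid label (0..3) and the full patch must fit inside the volume
    (overrunning centers are skipped).  ``max_patches`` subsamples with a
    seeded RNG, optionally class-balanced.
    """
    X, Y, Z, N = volume.values.shape
    half = patch_size // 2
    lo, hi = half, np.array([X, Y, Z]) - half
    grid = np.meshgrid(*(np.arange(lo, h, stride) for h in hi), indexing="ij")
    centers = np.stack([g.ravel() for g in grid], axis=1)
    ok = volume.mask[centers[:, 0], centers[:, 1], centers[:, 2]]
    lab = labels[centers[:, 0], centers[:, 1], centers[:, 2]]
    ok &= lab < 4
    centers, lab = centers[ok], lab[ok].astype(np.intp)

    rng = np.random.default_rng(seed)
    if max_patches is not None and len(centers) > max_patches:
        if balance:
            per_class = max_patches // 4
            keep = []
            for c in range(4):
                idx = np.flatnonzero(lab == c)
                take = min(per_class, len(idx))
                keep.append(rng.choice(idx, size=take, replace=False))
            keep = np.sort(np.concatenate(keep))
        else:
            keep = np.sort(rng.choice(len(centers), size=max_patches,
                                      replace=False))
        centers, lab = centers[keep], lab[keep]

    M = len(centers)
    patches = np.empty((M, patch_size, patch_size, patch_size, N),
                       dtype=volume.values.dtype)
    for i, (x, y, z) in enumerate(centers):
        patches[i] = volume.values[x - half:x + half + 1,
                                   y - half:y + half + 1,
                                   z - half:z + half + 1]
    return PatchDataset(patches=patches, labels=lab, coords=centers,
                        scheme=volume.scheme,
                        scan_ids=np.full(M, scan_id, dtype=np.intp))


def focal_loss(probs: np.ndarray, labels: np.ndarray,
               gamma: float = FOCAL_GAMMA,
               alpha: tuple[float, ...] = FOCAL_ALPHA) -> float:
    """Batch-mean focal loss ``-alpha_y (1 - p_y)^gamma log p_y``.

    ``probs`` are class probabilities (positive, rows summing to 1);
    ``p_y`` is clamped at 1e-8 before the log.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if (probs <= 0).any() or np.abs(probs.sum(axis=1) - 1).max() > 1e-6:
        raise ValueError("probs must be positive and sum to 1 per row")
    p_y = np.clip(probs[np.arange(len(labels)), labels], 1e-8, 1.0)
    a_y = np.asarray(alpha)[labels]
    return float(np.mean(-a_y * (1 - p_y) ** gamma * np.log(p_y)))


def focal_loss_with_grad(logits: np.ndarray, labels: np.ndarray,
                         gamma: float = FOCAL_GAMMA,
                         alpha: tuple[float, ...] = FOCAL_ALPHA
                         ) -> tuple[float, np.ndarray]:
    """Focal loss on logits plus its gradient with respect to the logits."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    B = len(labels)
    idx = np.arange(B)
    p_y = np.clip(probs[idx, labels], 1e-8, 1.0)
    a_y = np.asarray(alpha)[labels]
    loss = float(np.mean(-a_y * (1 - p_y) ** gamma * np.log(p_y)))
    # dL/dp_y, then chain through softmax: dp_y/dz_k = p_y (delta_yk - p_k)
    dLdp = a_y * (gamma * (1 - p_y) ** (gamma - 1) * np.log(p_y)
                  - (1 - p_y) ** gamma / p_y)
    grad = -probs * (dLdp * p_y)[:, None]
    grad[idx, labels] += dLdp * p_y
    return loss, grad / B


def octahedral_augment(patch: np.ndarray, scheme: SamplingScheme,
                       R: np.ndarray, kappa: float = 10.0) -> np.ndarray:
    """Rotate one cubic patch by an octahedral element, signals included.

    The voxel grid permutes exactly; each voxel's spherical signal is
    re-expressed at the *original* b-vectors by Watson interpolation from the
    rotated scheme, so downstream featurization is unchanged.
    """
    oct24 = octahedral_group().elements
    if not any(np.array_equal(np.round(R).astype(int), E) for E in oct24):
        raise ValueError("R must be an element of the octahedral group")
    rotated_grid = rotate_grid_exact(patch, R, spatial_axes=(0, 1, 2))
    rot = rotate_scheme(scheme, R)
    W = watson_weights(scheme.directions, rot.directions, kappa)
    return rotated_grid @ W.weights.T.astype(patch.dtype)


def build_rotated_testset(dataset: PatchDataset, seed: int = 0,
                          kappa: float = 10.0) -> PatchDataset:
    """One independent random octahedral rotation per patch; labels unchanged."""
    oct24 = octahedral_group().elements
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 24, size=len(dataset))
    patches = np.empty_like(dataset.patches)
    for i, r in enumerate(draws):
        patches[i] = octahedral_augment(dataset.patches[i], dataset.scheme,
                                        oct24[r], kappa=kappa)
    return PatchDataset(patches=patches, labels=dataset.labels.copy(),
                        coords=dataset.coords.copy(), scheme=dataset.scheme,
                        scan_ids=None if dataset.scan_ids is None
                        else dataset.scan_ids.copy())


@dataclass(frozen=True)
class EvalReport:
    """Per-class accuracy and Dice plus overall accuracy, mean +- sd over scans.

    Entries are NaN-free: a class absent from every scan would be flagged in
    ``missing``; per-scan values where a class is absent are excluded from
    the mean.
    """

    class_accuracy: np.ndarray  # (4,)
    class_accuracy_sd: np.ndarray
    class_dice: np.ndarray  # (4,)
    class_dice_sd: np.ndarray
    overall_accuracy: float
    overall_accuracy_sd: float
    n_scans: int
    missing: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "class_accuracy": self.class_accuracy.tolist(),
            "class_accuracy_sd": self.class_accuracy_sd.tolist(),
            "class_dice": self.class_dice.tolist(),
            "class_dice_sd": self.class_dice_sd.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "overall_accuracy_sd": self.overall_accuracy_sd,
            "n_scans": self.n_scans,
            "missing": list(self.missing),
        }


def _scan_metrics(pred: np.ndarray, lab: np.ndarray,
                  n_classes: int = 4) -> tuple[np.ndarray, np.ndarray, float]:
    acc = np.full(n_classes, np.nan)
    dice = np.full(n_classes, np.nan)
    for c in range(n_classes):
        tp = int(((pred == c) & (lab == c)).sum())
        fp = int(((pred == c) & (lab != c)).sum())
        fn = int(((pred != c) & (lab == c)).sum())
        if tp + fn > 0:
            acc[c] = tp / (tp + fn)
            dice[c] = 2 * tp / (2 * tp + fp + fn)
    overall = float((pred == lab).mean())
    return acc, dice, overall


def evaluate(predictions: np.ndarray, labels: np.ndarray,
             scan_ids: np.ndarray | None = None,
             n_classes: int = 4) -> EvalReport:
    """Recall-style per-class accuracy, per-class Dice and overall accuracy.

    Per-class accuracy is #correct / #class-samples; Dice is
    2TP / (2TP + FP + FN).  With ``scan_ids`` the metrics are aggregated as
    mean +- sd over scan-level values; scans lacking a class are excluded
    from that class's mean (classes absent everywhere are listed in
    ``missing``).
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if scan_ids is None:
        scan_ids = np.zeros(len(labels), dtype=np.intp)
    scans = np.unique(scan_ids)
    accs, dices, overalls = [], [], []
    for s in scans:
        sel = scan_ids == s
        a, d, o = _scan_metrics(predictions[sel], labels[sel], n_classes)
        accs.append(a)
        dices.append(d)
        overalls.append(o)
    accs, dices = np.array(accs), np.array(dices)
    overalls = np.array(overalls)
    import warnings

    with warnings.catch_warnings():
        # all-NaN columns (class absent in every scan) are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_acc = np.nanmean(accs, axis=0)
        sd_acc = np.nanstd(accs, axis=0)
        mean_dice = np.nanmean(dices, axis=0)
        sd_dice = np.nanstd(dices, axis=0)
    missing = tuple(int(c) for c in range(n_classes)
                    if np.isnan(accs[:, c]).all())
    for c in missing:
        mean_acc[c] = sd_acc[c] = mean_dice[c] = sd_dice[c] = 0.0
    return EvalReport(
        class_accuracy=mean_acc, class_accuracy_sd=sd_acc,
        class_dice=mean_dice, class_dice_sd=sd_dice,
        overall_accuracy=float(overalls.mean()),
        overall_accuracy_sd=float(overalls.std()),
        n_scans=len(scans), missing=missing)


def performance_drop_map(c_reference: float, c_perturbed: float,
                         alpha: float = 20.0,
                         formula: str = "exp_decay") -> float:
    """Map a performance ratio ``x = c_reference / c_perturbed`` to a drop score.

    ``exp_decay`` returns ``exp(-alpha x)``; ``logistic`` returns
    ``1 / (1 + exp(-alpha (x - 1)))`` (0.5 at no change, increasing with the
    drop).  Both are exposed because the published formula is ambiguous; the
    formula used should be recorded alongside any reported number.
    """
    if not (0 < c_reference <= 1 and 0 < c_perturbed <= 1):
        raise ValueError("metrics must lie in (0, 1]")
    x = c_reference / c_perturbed
    if formula == "exp_decay":
        return float(np.exp(-alpha * x))
    if formula == "logistic":
        return float(1.0 / (1.0 + np.exp(-alpha * (x - 1.0))))
    raise ValueError(f"unknown formula {formula!r}")


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)


def train(network: BuiltNetwork, dataset: PatchDataset,
          batch_size: int = 100, lr: float = 0.001, epochs: int = 10,
          seed: int = 0, gamma: float = FOCAL_GAMMA,
          alpha: tuple[float, ...] = FOCAL_ALPHA,
          augment_seed: int | None = None,
          verbose: bool = False) -> TrainHistory:
    """Seeded mini-batch Adam minimizing the focal loss.

    Deterministic given the seed (single-threaded numpy).  With
    ``augment_seed`` set, every batch is rotated on the fly by octahedral
    elements before featurization.  Raises on divergence (non-finite loss).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    aug_rng = (np.random.default_rng(augment_seed)
               if augment_seed is not None else None)
    oct24 = octahedral_group().elements if aug_rng is not None else None
    opt = nn.Adam(network.parameters(), lr=lr)
    history = TrainHistory()
    M = len(dataset)
    for epoch in range(epochs):
        order = rng.permutation(M)
        losses = []
        for start in range(0, M, batch_size):
            idx = order[start:start + batch_size]
            patches = dataset.patches[idx]
            if aug_rng is not None:
                patches = patches.copy()
                for i in range(len(patches)):
                    R = oct24[aug_rng.integers(0, 24)]
                    patches[i] = octahedral_augment(
                        patches[i], dataset.scheme, R, kappa=network.kappa)
            x = network.featurize(patches, dataset.scheme)
            logits = network.forward(x)
            loss, grad = focal_loss_with_grad(logits, dataset.labels[idx],
                                              gamma=gamma, alpha=alpha)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            opt.zero_grad()
            network.backward(grad.astype(logits.dtype))
            opt.step()
            losses.append(loss)
        history.epoch_loss.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: loss {history.epoch_loss[-1]:.4f}")
    return history
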