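"""Synthetic head phantoms with facial features, and simulated defacing.

The generator replaces a clinical scan registry as the test substrate. A
phantom is a head-shaped ellipsoid with an interior brain compartment and
four surface features (nose, two eyes, mouth) modeled as ellipsoidal
protrusions on the anterior face. Tissue intensities are piecewise constant
plus Gaussian noise inside the head; the background is exactly zero so the
intensity support coincides with the head mask.

Simulated defacing spans the observed failure modes of real defacing tools:
complete feature removal, residual partial features (removed surface-inward
so a partial removal leaves a realistic shell rather than speckle), a tiny
global intensity perturbation touching nearly every voxel, and clipping of
brain tissue.

Subjects contribute several scans; all scans of one subject share a shape
jitter so within-subject correlation exists and group-aware cross-validation
has something to protect against.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd

from .volume_io import Mask, Volume

__all__ = [
    "FACIAL_FEATURES",
    "DEFACING_METHODS",
    "PhantomSpec",
    "Phantom",
    "DefaceSimSpec",
    "GroundTruthRule",
    "generate_phantom",
    "simulate_defacing",
    "label",
    "generate_cohort",
]

FACIAL_FEATURES = ("nose", "left_eye", "right_eye", "mouth")
DEFACING_METHODS = ("pydeface", "quickshear", "fsldeface", "mrideface")


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable sub-seed from a master seed and a token path (below 2**31)."""
    h = hashlib.sha256(
        ("|".join([str(master_seed), *map(str, tokens)])).encode()
    ).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic head scan.

    Semi-axes and feature sizes are fractions of the grid edge. ``jitter``
    is a multiplicative shape perturbation (one factor per head semi-axis)
    shared across all scans of one subject.
    """

    grid_size: int = 96
    head_semiaxes: tuple = (0.30, 0.36, 0.34)
    brain_scale: float = 0.62   # brain semi-axes as a fraction of the head's
    features: tuple = FACIAL_FEATURES
    tissue_intensity: float = 0.55
    brain_intensity: float = 0.85
    feature_intensity: float = 0.70
    noise_sigma: float = 0.02
    subject_id: str = "sub-000"
    scan_id: str = "scan-000"
    jitter: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0 < self.brain_scale < 1:
            raise ValueError("brain must be strictly inside the head")
        unknown = set(self.features) - set(FACIAL_FEATURES)
        if unknown:
            raise ValueError(f"unknown facial features: {sorted(unknown)}")


@dataclasses.dataclass
class Phantom:
    """A generated scan: volume, masks, and per-feature voxel masks."""

    volume: Volume
    head: Mask
    brain: Mask
    feature_masks: dict
    spec: PhantomSpec


# outward surface directions and ellipsoid semi-axes (fractions of grid
# edge) for each facial feature; the face points along +y, superior is +z
_FEATURE_GEOMETRY = {
    "nose": ((0.0, 0.97, -0.24), (0.065, 0.11, 0.075)),
    "left_eye": ((-0.38, 0.88, 0.28), (0.055, 0.075, 0.055)),
    "right_eye": ((0.38, 0.88, 0.28), (0.055, 0.075, 0.055)),
    "mouth": ((0.0, 0.90, -0.44), (0.12, 0.055, 0.05)),
}


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    d = sum(
        ((coords[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3)
    )
    return d <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically build one phantom scan from its spec."""
    n = spec.grid_size
    rng = np.random.default_rng(spec.seed)
    coords = np.indices((n, n, n), dtype=np.float64)
    center = np.array([(n - 1) / 2.0] * 3)
    head_ax = np.array(spec.head_semiaxes) * np.array(spec.jitter) * n

    skull = _ellipsoid(coords, center, head_ax)
    brain_center = center + np.array([0.0, -0.04 * n, 0.03 * n])
    brain_ax = head_ax * spec.brain_scale
    brain = _ellipsoid(coords, brain_center, brain_ax)
    if np.any(brain & ~skull):
        raise ValueError("brain compartment extends outside the head")

    feature_masks = {}
    head = skull.copy()
    for name in spec.features:
        direction, size = _FEATURE_GEOMETRY[name]
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        # point on the head-ellipsoid surface along the outward direction
        r = 1.0 / np.sqrt(np.sum((d / head_ax) ** 2))
        surface = center + r * d
        fmask = _ellipsoid(coords, surface, np.asarray(size) * n)
        fmask &= ~brain
        feature_masks[name] = fmask
        head |= fmask

    intensities = np.zeros((n, n, n))
    intensities[head] = spec.tissue_intensity
    for fmask in feature_masks.values():
        intensities[fmask & ~skull] = spec.feature_intensity
    intensities[brain] = spec.brain_intensity
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=intensities.shape)
        intensities[head] = np.clip(
            intensities[head] + noise[head], 0.08, 1.0
        )

    volume = Volume(
        intensities=intensities,
        affine=np.eye(4),
        scan_id=spec.scan_id,
        subject_id=spec.subject_id,
    )
    return Phantom(
        volume=volume,
        head=Mask(head, kind="head", source_scan_id=spec.scan_id),
        brain=Mask(brain, kind="brain", source_scan_id=spec.scan_id),
        feature_masks=feature_masks,
        spec=spec,
    )


@dataclasses.dataclass
class DefaceSimSpec:
    """Parameters of one simulated defacing outcome.

    removal
        Per-feature removal extent in [0, 1]; 1 means fully removed.
    global_perturbation
        Tiny additive intensity applied to every voxel, emulating tools that
        perturb intensities across nearly the whole scan.
    brain_clip
        Fraction of brain-mask voxels zeroed, emulating accidental damage to
        brain tissue.
    """

    removal: dict
    global_perturbation: float = 0.0
    brain_clip: float = 0.0
    method_tag: str = "pydeface"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in self.removal.items():
            if name not in FACIAL_FEATURES:
                raise ValueError(f"unknown feature {name!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError("removal extents must lie in [0, 1]")
        if not 0.0 <= self.brain_clip <= 1.0:
            raise ValueError("brain_clip must lie in [0, 1]")
        if self.method_tag not in DEFACING_METHODS:
            raise ValueError(f"unknown defacing method {self.method_tag!r}")


def simulate_defacing(phantom: Phantom, sim: DefaceSimSpec) -> Volume:
    """Apply a simulated defacing outcome to a phantom scan.

    Feature voxels are zeroed in surface-inward order (outermost first along
    the feature's outward direction), then the global perturbation is added
    to all voxels, then the requested fraction of brain voxels is zeroed.
    Deterministic given ``sim.seed``.
    """
    rng = np.random.default_rng(sim.seed)
    out = phantom.volume.intensities.copy()

    for name, r in sim.removal.items():
        if r <= 0.0 or name not in phantom.feature_masks:
            continue
        fmask = phantom.feature_masks[name]
        idx = np.argwhere(fmask)
        if idx.size == 0:
            continue
        direction = np.asarray(_FEATURE_GEOMETRY[name][0], dtype=float)
        direction /= np.linalg.norm(direction)
        depth = idx @ direction
        order = np.argsort(-depth, kind="stable")  # outermost first
        n_remove = int(np.ceil(r * len(order)))
        sel = idx[order[:n_remove]]
        out[sel[:, 0], sel[:, 1], sel[:, 2]] = 0.0

    if sim.global_perturbation != 0.0:
        out = out + sim.global_perturbation

    if sim.brain_clip > 0.0:
        bidx = np.argwhere(phantom.brain.voxels)
        n_clip = int(np.floor(sim.brain_clip * len(bidx)))
        if n_clip > 0:
            sel = bidx[rng.choice(len(bidx), size=n_clip, replace=False)]
            out[sel[:, 0], sel[:, 1], sel[:, 2]] = 0.0

    return Volume(
        intensities=out,
        affine=phantom.volume.affine,
        scan_id=phantom.volume.scan_id,
        subject_id=phantom.volume.subject_id,
    )


@dataclasses.dataclass
class GroundTruthRule:
    """Label rule mirroring the manual strict/lenient review criteria.

    A feature counts as *residual* when its removal extent is below
    ``residual_threshold``. Strict success requires no residual feature at
    all; lenient success tolerates a minimal residual trace (removal extent
    at least ``minimal_residual``) of at most one feature.
    """

    criterion: str = "lenient"
    residual_threshold: float = 0.95
    minimal_residual: float = 0.5

    def __post_init__(self) -> None:
        if self.criterion not in ("strict", "lenient"):
            raise ValueError("criterion must be 'strict' or 'lenient'")


def label(sim: DefaceSimSpec, rule: GroundTruthRule) -> int:
    """0 = successfully defaced, 1 = insufficiently defaced."""
    residuals = [
        r for r in sim.removal.values() if r < rule.residual_threshold
    ]
    if rule.criterion == "strict":
        return 0 if not residuals else 1
    if not residuals:
        return 0
    if len(residuals) == 1 and residuals[0] >= rule.minimal_residual:
        return 0
    return 1


# ---------------------------------------------------------------------------
# cohort generation

# outcome templates: (name, lenient label, strict label)
_TEMPLATES = ("clean", "single_minimal", "single_severe", "multi_residual")

# relative propensity of each method to produce a failed defacing; used to
# distribute the requested number of failures across methods
_METHOD_FAIL_WEIGHT = {
    "pydeface": 0.5,
    "quickshear": 0.8,
    "fsldeface": 0.9,
    "mrideface": 2.5,
}


def _draw_sim(template: str, rng: np.random.Generator, method: str,
              seed: int) -> DefaceSimSpec:
    removal = {f: 1.0 for f in FACIAL_FEATURES}
    if template == "single_minimal":
        f = FACIAL_FEATURES[rng.integers(len(FACIAL_FEATURES))]
        removal[f] = float(rng.uniform(0.5, 0.94))
    elif template == "single_severe":
        f = FACIAL_FEATURES[rng.integers(len(FACIAL_FEATURES))]
        removal[f] = float(rng.uniform(0.05, 0.45))
    elif template == "multi_residual":
        k = int(rng.integers(2, len(FACIAL_FEATURES) + 1))
        chosen = rng.choice(len(FACIAL_FEATURES), size=k, replace=False)
        for i in chosen:
            removal[FACIAL_FEATURES[i]] = float(rng.uniform(0.0, 0.7))
    elif template != "clean":
        raise ValueError(f"unknown template {template!r}")

    delta = 0.0
    p_perturb = 0.6 if method == "mrideface" else 0.2
    if rng.random() < p_perturb:
        delta = float(rng.uniform(0.001, 0.004))
    clip = float(rng.uniform(0.0, 0.05)) if rng.random() < 0.1 else 0.0
    return DefaceSimSpec(
        removal=removal,
        global_perturbation=delta,
        brain_clip=clip,
        method_tag=method,
        seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    scans_per_subject: tuple = (1, 7),
    methods: tuple = DEFACING_METHODS,
    positive_fraction: float = 0.5,
    balance_criterion: str = "lenient",
    master_seed: int = 0,
    grid_size: int = 96,
    noise_sigma: float = 0.02,
    rule: GroundTruthRule | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Build a labeled synthetic cohort manifest.

    Each subject contributes a uniform number of scans within
    ``scans_per_subject``; each scan is "defaced" by every method in
    ``methods``, one manifest row per pair. Exactly
    ``round(positive_fraction * n_pairs)`` rows are failures under
    ``balance_criterion``; failures fall preferentially on methods with a
    higher failure propensity. Everything is reproducible from
    ``master_seed``. If ``out_dir`` is given, phantom and defaced volumes
    plus masks are written there as NIfTI.

    The manifest carries the full simulation parameters, so the strict and
    lenient labels can be re-derived from it exactly.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    rule = rule or GroundTruthRule()
    rng = np.random.default_rng(derive_seed(master_seed, "cohort"))

    rows = []
    for s in range(n_subjects):
        lo, hi = scans_per_subject
        n_scans = int(rng.integers(lo, hi + 1))
        subject = f"sub-{s:03d}"
        for t in range(n_scans):
            scan = f"{subject}_scan-{t:02d}"
            for method in methods:
                rows.append(
                    {"subject_id": subject, "scan_id": scan,
                     "method": method}
                )
    n_pairs = len(rows)
    n_pos = int(round(positive_fraction * n_pairs))
    if n_pos > n_pairs:
        raise ValueError("unsatisfiable class balance request")

    weights = np.array([_METHOD_FAIL_WEIGHT[r["method"]] for r in rows])
    weights = weights / weights.sum()
    pos_idx = set(
        rng.choice(n_pairs, size=n_pos, replace=False, p=weights).tolist()
    )

    strict_rule = GroundTruthRule(
        "strict", rule.residual_threshold, rule.minimal_residual
    )
    lenient_rule = GroundTruthRule(
        "lenient", rule.residual_threshold, rule.minimal_residual
    )

    for i, row in enumerate(rows):
        positive = i in pos_idx
        if balance_criterion == "lenient":
            options = (
                ("single_severe", "multi_residual")
                if positive
                else ("clean", "single_minimal")
            )
        else:
            options = (
                ("single_minimal", "single_severe", "multi_residual")
                if positive
                else ("clean",)
            )
        template = options[int(rng.integers(len(options)))]
        sim_seed = derive_seed(master_seed, "sim", row["scan_id"],
                               row["method"])
        sim = _draw_sim(template, rng, row["method"], sim_seed)
        row.update(
            {
                "template": template,
                "label_strict": label(sim, strict_rule),
                "label_lenient": label(sim, lenient_rule),
                "global_perturbation": sim.global_perturbation,
                "brain_clip": sim.brain_clip,
                "sim_seed": sim_seed,
            }
        )
        for f in FACIAL_FEATURES:
            row[f"removal_{f}"] = sim.removal[f]

    manifest = pd.DataFrame(rows)
    manifest.attrs["master_seed"] = master_seed
    manifest.attrs["grid_size"] = grid_size
    manifest.attrs["noise_sigma"] = noise_sigma

    if out_dir is not None:
        _write_cohort(manifest, grid_size, noise_sigma, master_seed, out_dir)
    return manifest


def phantom_for_row(
    row, grid_size: int, noise_sigma: float, master_seed: int
) -> Phantom:
    """Rebuild the phantom for one manifest row (jitter shared per subject)."""
    subj_rng = np.random.default_rng(
        derive_seed(master_seed, "jitter", row["subject_id"])
    )
    jitter = tuple(subj_rng.uniform(0.93, 1.07, size=3))
    spec = PhantomSpec(
        grid_size=grid_size,
        noise_sigma=noise_sigma,
        subject_id=row["subject_id"],
        scan_id=row["scan_id"],
        jitter=jitter,
        seed=derive_seed(master_seed, "phantom", row["scan_id"]),
    )
    return generate_phantom(spec)


def sim_from_row(row) -> DefaceSimSpec:
    """Reconstruct the defacing simulation spec from a manifest row."""
    return DefaceSimSpec(
        removal={f: float(row[f"removal_{f}"]) for f in FACIAL_FEATURES},
        global_perturbation=float(row["global_perturbation"]),
        brain_clip=float(row["brain_clip"]),
        method_tag=row["method"],
        seed=int(row["sim_seed"]),
    )


def _write_cohort(manifest, grid_size, noise_sigma, master_seed, out_dir):
    from pathlib import Path

    from .volume_io import save_mask, save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = set()
    for _, row in manifest.iterrows():
        ph = phantom_for_row(row, grid_size, noise_sigma, master_seed)
        if row["scan_id"] not in written:
            save_volume(ph.volume, out / f"{row['scan_id']}.nii.gz")
            save_mask(
                ph.brain, out / f"{row['scan_id']}_brainmask.nii.gz",
                affine=ph.volume.affine,
            )
            written.add(row["scan_id"])
        defaced = simulate_defacing(ph, sim_from_row(row))
        save_volume(
            defaced, out / f"{row['scan_id']}_{row['method']}.nii.gz"
        )
    manifest.to_csv(out / "manifest.csv", index=False)
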