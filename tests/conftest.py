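import numpy as np
import pytest

from defaceqc import (
    DefaceSimSpec,
    FACIAL_FEATURES,
    PhantomSpec,
    extract_pair_features,
    generate_phantom,
    simulate_defacing,
)

# small problem sizes keep the suite fast while exercising every code path
GRID = 48
RES = 64


@pytest.fixture(scope="session")
def phantom():
    """Default small phantom with noise."""
    return generate_phantom(
        PhantomSpec(grid_size=GRID, seed=11, scan_id="fix-a",
                    subject_id="sub-fix")
    )


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free, left/right symmetric phantom (for geometry checks)."""
    return generate_phantom(
        PhantomSpec(grid_size=GRID, seed=3, noise_sigma=0.0)
    )


def removal(**kwargs):
    """Removal dict with every facial feature fully removed by default."""
    r = {f: 1.0 for f in FACIAL_FEATURES}
    r.update(kwargs)
    return r


def pair_features(ph, sim: DefaceSimSpec, resolution: int = RES) -> dict:
    defaced = simulate_defacing(ph, sim)
    return extract_pair_features(
        ph.volume, defaced, ph.brain, resolution=resolution
    )


def separable_cohort_table(
    n_subjects: int = 60,
    noise_sigma: float = 0.02,
    master_seed: int = 0,
    grid_size: int = GRID,
    resolution: int = RES,
):
    """Two well-separated outcome classes: full removal vs two residual
    features. Subjects contribute 1-2 scans, each defaced by all four
    methods (one pair per scan/method), mirroring the multi-scan,
    multi-method cohort shape the group constraint exists for. Returns a
    modeling table with lenient labels (full removal -> 0, two residuals
    -> 1)."""
    import pandas as pd

    from defaceqc import DEFACING_METHODS, GroundTruthRule, label
    from defaceqc.features import extract_pair_features, modeling_table
    from defaceqc.phantom import derive_seed

    rows = []
    pair_idx = 0
    for s in range(n_subjects):
        subject = f"sub-{s:03d}"
        rng = np.random.default_rng(derive_seed(master_seed, "sep", s))
        jitter = tuple(rng.uniform(0.93, 1.07, size=3))
        n_scans = int(rng.integers(1, 3))
        for t in range(n_scans):
            ph = generate_phantom(
                PhantomSpec(
                    grid_size=grid_size,
                    noise_sigma=noise_sigma,
                    subject_id=subject,
                    scan_id=f"{subject}_scan-{t:02d}",
                    jitter=jitter,
                    seed=derive_seed(master_seed, "sep-phantom", s, t),
                )
            )
            for method in DEFACING_METHODS:
                if pair_idx % 2 == 0:
                    rem = removal()
                else:
                    feats = rng.choice(
                        len(FACIAL_FEATURES), size=2, replace=False
                    )
                    rem = removal(
                        **{
                            FACIAL_FEATURES[i]: float(rng.uniform(0.0, 0.5))
                            for i in feats
                        }
                    )
                sim = DefaceSimSpec(
                    removal=rem, method_tag=method,
                    seed=derive_seed(master_seed, "sep-sim", pair_idx),
                )
                row = extract_pair_features(
                    ph.volume, simulate_defacing(ph, sim), ph.brain,
                    resolution=resolution,
                )
                row["method"] = method
                for crit in ("strict", "lenient"):
                    row[f"label_{crit}"] = label(sim, GroundTruthRule(crit))
                rows.append(row)
                pair_idx += 1
    return modeling_table(pd.DataFrame(rows), criterion="lenient")


@pytest.fixture(scope="session")
def separable_table():
    return separable_cohort_table(n_subjects=60)
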