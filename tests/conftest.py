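"""Shared fixtures: synthetic structures are built once per session since
corner assembly (loop closure) is the expensive step."""

import numpy as np
import pytest

from betacorner.synthetic_data import (
    EnsembleSpec,
    build_ideal_hairpin,
    build_synthetic_corner,
    generate_ensemble,
)


@pytest.fixture(scope="session")
def corner():
    """Default right-handed corner (strands 6/8/6, loops 4/4) + ground truth."""
    return build_synthetic_corner((6, 8, 6), (4, 4), "right", seed=1)


@pytest.fixture(scope="session")
def left_corner():
    return build_synthetic_corner((6, 8, 6), (4, 4), "left", seed=1)


@pytest.fixture(scope="session")
def hairpin():
    return build_ideal_hairpin(6, 4, seed=1)


@pytest.fixture(scope="session")
def two_state_ensemble(corner):
    """200-frame ensemble with a planted 0.85/0.15 two-state split."""
    base, _gt = corner
    spec = EnsembleSpec(
        base=base,
        n_frames=200,
        noise_sigma=0.5,
        state_fractions=(0.85, 0.15),
        state_hinge_deg=(0.0, 60.0),
        seed=11,
    )
    st, labels = generate_ensemble(spec)
    return st, labels


def grid_min_rmsd(p, q):
    """Independent superposition oracle: brute-force minimisation of RMSD
    over rotations parameterised by Euler angles, on a coarse grid followed
    by two local refinements.  No SVD anywhere."""
    from scipy.spatial.transform import Rotation

    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def rmsd_at(a, b, c):
        r = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
        return float(np.sqrt(np.mean(np.sum((qc @ r.T - pc) ** 2, axis=1))))

    coarse = []
    for a in np.linspace(-np.pi, np.pi, 25):
        for b in np.linspace(0, np.pi, 13):
            for c in np.linspace(-np.pi, np.pi, 25):
                coarse.append((rmsd_at(a, b, c), (a, b, c)))
    coarse.sort(key=lambda t: t[0])
    # refine the best few basins: 4-point sets can have near-degenerate
    # local minima and a single-basin refinement may pick the wrong one
    overall = coarse[0][0]
    for _v, angles in coarse[:5]:
        best = (_v, angles)
        for width in (0.2, 0.02, 0.002):
            a0, b0, c0 = best[1]
            for a in a0 + np.linspace(-width, width, 11):
                for b in b0 + np.linspace(-width, width, 11):
                    for c in c0 + np.linspace(-width, width, 11):
                        v = rmsd_at(a, b, c)
                        if v < best[0]:
                            best = (v, (a, b, c))
        overall = min(overall, best[0])
    return overall


def mirror_structure(s):
    """x -> -x coordinate reflection of a structure (in place on a copy)."""
    import copy

    m = copy.deepcopy(s)
    flip = np.array([-1.0, 1.0, 1.0])
    for model in range(m.n_models):
        for res in m.residues(model=model):
            for a in res.atoms:
                a.coords = a.coords * flip
    return m
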