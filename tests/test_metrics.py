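"""Dice / Hausdorff metrics against brute-force oracles, and the compound
dice + cross-entropy training loss."""
import math

import numpy as np
import pytest

from hrstnet import (
    Tensor, dice_ce_loss, dice_score, extract_boundary, hausdorff95,
    hausdorff_distance, region_masks,
)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------
def test_dice_worked_examples():
    m = np.zeros((4, 4, 4), bool)
    m[:2] = True
    assert dice_score(m, m) == 1.0
    assert dice_score(m, ~m) == 0.0
    # |P| = 4, |G| = 6, |P n G| = 3  ->  2*3 / 10 = 0.6
    P = np.zeros(16, bool)
    G = np.zeros(16, bool)
    P[:4] = True
    G[1:7] = True
    assert dice_score(P, G) == pytest.approx(0.6)
    assert dice_score(np.zeros(3, bool), np.zeros(3, bool)) == 1.0


def test_dice_symmetry_random_pairs(rng):
    for _ in range(100):
        P = rng.random((6, 6, 6)) < 0.3
        G = rng.random((6, 6, 6)) < 0.3
        assert dice_score(P, G) == dice_score(G, P)


def test_dice_shape_mismatch():
    with pytest.raises(ValueError):
        dice_score(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------
def test_boundary_solid_cube_and_single_voxel():
    cube = np.zeros((5, 5, 5), bool)
    cube[1:4, 1:4, 1:4] = True
    b = extract_boundary(cube)
    assert len(b) == 26  # all but the centre voxel
    assert [2, 2, 2] not in b.tolist()
    single = np.zeros((3, 3, 3), bool)
    single[1, 1, 1] = True
    np.testing.assert_array_equal(extract_boundary(single), [[1, 1, 1]])


def test_boundary_of_hollow_shell_is_identity(rng):
    shell = np.zeros((7, 7, 7), bool)
    shell[1:6, 1:6, 1:6] = True
    shell[2:5, 2:5, 2:5] = False
    got = {tuple(v) for v in extract_boundary(shell)}
    # brute-force 6-neighbour check
    expect = set()
    for p in np.argwhere(shell):
        for ax in range(3):
            for d in (-1, 1):
                q = p.copy()
                q[ax] += d
                if (q < 0).any() or (q >= 7).any() or not shell[tuple(q)]:
                    expect.add(tuple(p))
    assert got == expect


def test_volume_border_counts_as_background():
    full = np.ones((3, 3, 3), bool)
    assert len(extract_boundary(full)) == 26  # centre is interior


# ---------------------------------------------------------------------------
# Hausdorff
# ---------------------------------------------------------------------------
def _brute_hd(P, G, spacing, percentile):
    sp = np.asarray(spacing, float)
    pb = extract_boundary(P) * sp
    gb = extract_boundary(G) * sp
    d = np.sqrt(((pb[:, None, :] - gb[None, :, :]) ** 2).sum(-1))
    return max(np.percentile(d.min(1), percentile),
               np.percentile(d.min(0), percentile))


def test_hausdorff_worked_examples():
    m = np.zeros((4, 4, 4), bool)
    m[1:3, 1:3, 1:3] = True
    assert hausdorff_distance(m, m) == 0.0
    a = np.zeros((1, 1, 6), bool)
    b = np.zeros((1, 1, 6), bool)
    a[0, 0, 0] = True
    b[0, 0, 5] = True
    assert hausdorff_distance(a, b) == pytest.approx(5.0)


def test_hausdorff_empty_mask_conventions():
    empty = np.zeros((3, 3, 3), bool)
    some = ~empty.copy()
    assert hausdorff95(empty, empty) == 0.0
    assert math.isnan(hausdorff95(empty, some))
    assert math.isnan(hausdorff95(some, empty))


def test_hausdorff_matches_brute_force_all_pairs(rng):
    """100 random 16^3 mask pairs vs the O(|P|*|G|) double-loop oracle."""
    for i in range(100):
        P = rng.random((16, 16, 16)) < 0.1
        G = rng.random((16, 16, 16)) < 0.1
        if not P.any() or not G.any():
            continue
        for q in (95.0, 100.0):
            ours = hausdorff_distance(P, G, percentile=q)
            assert ours == pytest.approx(_brute_hd(P, G, (1, 1, 1), q), abs=1e-9)


def test_hd95_not_larger_than_hd100_and_symmetric(rng):
    for _ in range(20):
        P = rng.random((10, 10, 10)) < 0.15
        G = rng.random((10, 10, 10)) < 0.15
        if not P.any() or not G.any():
            continue
        assert hausdorff95(P, G) <= hausdorff_distance(P, G) + 1e-12
        assert hausdorff95(P, G) == hausdorff95(G, P)
        assert hausdorff_distance(P, G) == hausdorff_distance(G, P)


def test_spacing_scales_distances_exactly(rng):
    P = rng.random((8, 8, 8)) < 0.2
    G = rng.random((8, 8, 8)) < 0.2
    a = hausdorff95(P, G, spacing=(1, 1, 1))
    b = hausdorff95(P, G, spacing=(2, 2, 2))
    assert b == pytest.approx(2 * a)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------
def test_region_masks_nesting(rng):
    lab = np.zeros((6, 6, 6), np.uint8)
    r = region_masks(lab)
    assert not any(m.any() for m in r.values())
    lab[3, 3, 3] = 3  # a single enhancing voxel is in all three regions
    r = region_masks(lab)
    assert r["ET"][3, 3, 3] and r["TC"][3, 3, 3] and r["WT"][3, 3, 3]
    for _ in range(20):
        lab = rng.integers(0, 4, (8, 8, 8)).astype(np.uint8)
        r = region_masks(lab)
        assert (r["WT"] >= r["TC"]).all() and (r["TC"] >= r["ET"]).all()
        np.testing.assert_array_equal(
            r["TC"], np.isin(lab, [1, 3]))  # set-union oracle
        np.testing.assert_array_equal(r["WT"], lab > 0)
    with pytest.raises(ValueError):
        region_masks(lab, scheme="nope")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------
def test_loss_vanishes_for_confident_correct_prediction(rng):
    target = rng.integers(0, 3, (1, 4, 4, 4))
    onehot = np.moveaxis(np.eye(3, dtype=np.float32)[target], -1, 1)
    scores = Tensor(onehot * 200.0 - 100.0)
    assert dice_ce_loss(scores, target).item() == pytest.approx(0.0, abs=1e-3)


def test_uniform_logits_ce_is_log2():
    scores = Tensor(np.zeros((1, 2, 4, 4, 4), np.float32))
    target = np.zeros((1, 4, 4, 4), np.int64)
    target[0, :2] = 1
    loss = dice_ce_loss(scores, target).item()
    # CE part is ln 2 per voxel; the dice part for the foreground class is
    # 1 - 2*0.5|G| / (0.5 N + |G|)
    n, g = 64, 32
    expect = math.log(2.0) + 1 - 2 * 0.5 * g / (0.5 * n + g)
    assert loss == pytest.approx(expect, abs=1e-4)


def test_loss_shape_mismatch():
    with pytest.raises(ValueError):
        dice_ce_loss(Tensor(np.zeros((1, 2, 4, 4, 4), np.float32)),
                     np.zeros((1, 5, 4, 4), np.int64))


def test_loss_decreases_under_gradient_descent(rng):
    """50 plain gradient steps on a fixed tiny batch reduce the loss."""
    from hrstnet._tensor import Parameter
    x = rng.standard_normal((1, 2, 4, 4, 4)).astype(np.float32)
    target = (x[:, 0] > 0).astype(np.int64)
    w = Parameter(rng.standard_normal((2, 2)).astype(np.float32) * 0.1)
    losses = []
    for _ in range(50):
        w.grad = None
        scores = (Tensor(np.moveaxis(x, 1, -1)) @ w)
        scores = scores.transpose(0, 4, 1, 2, 3)
        loss = dice_ce_loss(scores, target)
        loss.backward()
        losses.append(loss.item())
        w.data -= 0.5 * w.grad
    assert losses[-1] < losses[0] * 0.7
    assert all(l >= 0 for l in losses)
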