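import numpy as np
import pytest

from scatterkin.formfactors import ATOMIC_NUMBER, FormFactorModel
from scatterkin.geometry import Geometry
from scatterkin.iam import DiffPattern, Pattern, debye_pattern, mixture_pattern, percent_difference
from scatterkin.structures import reference_structures


@pytest.fixture(scope="module")
def ff():
    return FormFactorModel()


def mc_orientation_average(geom, q, ff, n_orient=100_000, seed=0):
    """Brute-force oracle: average |sum_i f_i exp(i q z . R r_i)|^2 over
    uniformly random rigid orientations.  Returns (mean, standard error)."""
    rng = np.random.default_rng(seed)
    f = np.stack([ff.evaluate(s, q) for s in geom.symbols])  # (n, nq)
    # random rotations via normalized quaternions
    u = rng.normal(size=(n_orient, 4))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    w, x, y, z = u.T
    # third row of the rotation matrix (lab z axis in body frame)
    r3 = np.stack([2 * (x * z - w * y), 2 * (y * z + w * x),
                   1 - 2 * (x * x + y * y)], axis=1)  # (n_orient, 3)
    proj = r3 @ geom.coords.T  # (n_orient, n_atoms): z-components
    means = np.empty(q.size)
    errs = np.empty(q.size)
    for k, qk in enumerate(q):
        amp = (f[:, k][None, :] * np.exp(1j * qk * proj)).sum(axis=1)
        inten = np.abs(amp) ** 2
        means[k] = inten.mean()
        errs[k] = inten.std(ddof=1) / np.sqrt(n_orient)
    return means, errs


def test_single_sulfur_atom_is_squared_form_factor(ff):
    q = np.linspace(0.0, 4.0, 9)
    g = Geometry(("S",), np.zeros((1, 3)))
    pat = debye_pattern(g, q, ff)
    np.testing.assert_allclose(pat.intensity, ff.evaluate("S", q) ** 2, rtol=1e-12)
    assert pat.intensity[0] == pytest.approx(ATOMIC_NUMBER["S"] ** 2, rel=1e-3)


def test_diatomic_closed_form(ff):
    r = 1.89
    q = np.linspace(0.0, 6.0, 50)
    g = Geometry(("S", "S"), np.array([[0, 0, 0], [r, 0, 0]], float))
    pat = debye_pattern(g, q, ff)
    fs = ff.evaluate("S", q)
    with np.errstate(invalid="ignore"):
        sinc = np.where(q == 0, 1.0, np.sin(q * r) / (q * r))
    np.testing.assert_allclose(pat.intensity, 2 * fs**2 * (1 + sinc), rtol=1e-12)
    # the interference term decays: large-q intensity approaches 2 f^2
    tail = np.abs(pat.intensity[-5:] / (2 * fs[-5:] ** 2) - 1.0)
    assert tail.max() < 1.0 / (q[-5] * r)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_debye_matches_monte_carlo_orientation_average(ff, seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 7)
    symbols = tuple(rng.choice(["H", "C", "S"], size=n))
    geom = Geometry(symbols, rng.uniform(-1.5, 1.5, (n, 3)))
    q = np.linspace(0.2, 4.0, 8)
    expected = debye_pattern(geom, q, ff).intensity
    mc, se = mc_orientation_average(geom, q, ff, n_orient=100_000, seed=seed + 10)
    assert np.all(np.abs(mc - expected) < 3 * se)


def test_forward_intensity_is_squared_electron_count(ff):
    rng = np.random.default_rng(3)
    for _ in range(5):
        n = rng.integers(1, 8)
        symbols = tuple(rng.choice(["H", "C", "S"], size=n))
        geom = Geometry(symbols, rng.uniform(-2, 2, (n, 3)))
        z_sum = sum(ATOMIC_NUMBER[s] for s in symbols)
        i0 = debye_pattern(geom, np.array([0.0]), ff).intensity[0]
        assert i0 == pytest.approx(z_sum**2, rel=2e-3)


def test_debye_invariant_under_rigid_motion(ff):
    rng = np.random.default_rng(4)
    geom = Geometry(("S", "C", "C", "H"), rng.uniform(-1, 1, (4, 3)))
    q = np.linspace(0.5, 4.5, 20)
    base = debye_pattern(geom, q, ff).intensity
    # random rotation + translation
    a = rng.normal(size=(3, 3))
    rot, _ = np.linalg.qr(a)
    moved = geom.rotated(rot).translated([5.0, -2.0, 1.0])
    np.testing.assert_allclose(debye_pattern(moved, q, ff).intensity, base, rtol=1e-10)


def test_mixture_is_additive_and_permutation_invariant(ff):
    q = np.linspace(0.5, 4.5, 20)
    refs = reference_structures()
    frags = refs["FA-2"]
    total = mixture_pattern(frags, q, ff).intensity
    summed = sum(debye_pattern(g, q, ff).intensity for g in frags)
    np.testing.assert_allclose(total, summed, rtol=1e-12)
    np.testing.assert_allclose(
        mixture_pattern(frags[::-1], q, ff).intensity, total, rtol=1e-12)


def test_mixture_of_two_atoms_and_electron_counting(ff):
    q = np.array([0.0, 1.0])
    s = Geometry(("S",), np.zeros((1, 3)))
    two = mixture_pattern([s, s], q, ff).intensity
    np.testing.assert_allclose(two, 2 * ff.evaluate("S", q) ** 2, rtol=1e-12)
    # FB channel at q=0: (sum Z of C4H8)^2 + (sum Z of S2)^2 = 32^2 + 32^2
    fb = reference_structures()["FB"]
    i0 = mixture_pattern(fb, np.array([0.0]), ff).intensity[0]
    assert i0 == pytest.approx(2048.0, rel=2e-3)
    with pytest.raises(ValueError):
        mixture_pattern([], q, ff)


def test_percent_difference_identities(ff):
    q = np.linspace(0.5, 4.5, 30)
    off = debye_pattern(reference_structures()["DT"][0], q, ff)
    same = percent_difference(off, off)
    assert np.all(same.values == 0.0)
    up = Pattern(q, 1.01 * off.intensity)
    np.testing.assert_allclose(percent_difference(up, off).values, 1.0, rtol=1e-10)
    with pytest.raises(ValueError):
        percent_difference(Pattern(q[:-1], off.intensity[:-1]), off)
    with pytest.raises(ValueError):
        percent_difference(off, Pattern(q, np.zeros_like(q)))


def test_dissociation_gives_negative_low_q_lobe(ff):
    """Fragmentation depletes the coherent low-q scattering: the percent
    difference of the two-body channel against intact dithiane is negative
    at low momentum transfer."""
    q = np.linspace(0.5, 4.5, 60)
    refs = reference_structures()
    on = mixture_pattern(refs["FB"], q, ff)
    off = mixture_pattern(refs["DT"], q, ff)
    diff = percent_difference(on, off)
    low = diff.values[q < 1.1]
    assert np.all(low < 0)


def test_diffpattern_io_roundtrip(tmp_path, ff):
    q = np.linspace(0.5, 4.5, 30)
    refs = reference_structures()
    diff = percent_difference(mixture_pattern(refs["FB"], q, ff),
                              mixture_pattern(refs["DT"], q, ff))
    diff = DiffPattern(diff.q, diff.values, sigma=np.full_like(q, 0.1))
    path = tmp_path / "fb.txt"
    diff.save(path)
    back = DiffPattern.load(path)
    np.testing.assert_allclose(back.values, diff.values, rtol=1e-8)
    np.testing.assert_allclose(back.sigma, diff.sigma, rtol=1e-8)
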