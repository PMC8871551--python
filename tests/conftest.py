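import numpy as np
import pytest

from porodiff import map_engine as me
from porodiff import synthetic_data as sd
from porodiff.dielectric_lpt import LPTParams


@pytest.fixture(scope="session")
def alpha_protocol():
    return sd.default_alpha_protocol()


@pytest.fixture(scope="session")
def md_protocol():
    return sd.default_md_protocol()


@pytest.fixture(scope="session")
def lpt_default():
    return LPTParams(Gamma=2.0, phi0=0.8, var=0.01)


def run_scenario(seed: int, matrix: int = 128, snr: float = 50.0):
    """Full three-sample pipeline: per-sample Mα and MD ROI distributions."""
    table = sd.three_sample_scenario(seed=seed, matrix_size=matrix, snr=snr)
    ap = sd.default_alpha_protocol()
    mp = sd.default_md_protocol()
    out = {}
    for label, S, spec in table.records:
        s_alpha = sd.make_dwi_series(spec, ap, branch="alpha")
        s_md = sd.make_dwi_series(spec, mp, branch="md")
        malpha = me.mean_alpha_map(me.alpha_maps_by_direction(s_alpha, ap))
        md = me.md_map(s_md, mp)
        center = (spec.fov / 2, spec.fov / 2)
        radius = 0.8 * spec.roi_radius_frac * spec.fov
        out[label] = {
            "S": S,
            "alpha_mean": spec.alpha_mean,
            "Malpha": me.roi_distribution(malpha, center, radius,
                                          s_alpha.voxel_size),
            "MD": me.roi_distribution(md, center, radius, s_md.voxel_size),
        }
    return out


def brute_force_eps_root(freq, params, n_levels=14, grid=41):
    """Independent complex-plane grid-scan root of the mixing law.

    Evaluates |residual| on a rectangular grid and repeatedly zooms on the
    minimising cell; no Newton step is ever taken, so this is independent of
    the production solver's path.
    """
    from porodiff import dielectric_lpt as dl

    g = dl._initial_guess(freq, params)
    wat = dl.water_eps(freq, params)
    re_lo, re_hi = params.eps_p * 0.3, abs(g.real) * 3 + params.eps_w * 3
    im_lo, im_hi = 0.0, abs(g.imag) * 3 + abs(wat.imag) * 1.5 + 1.0
    phi, mu_w = dl.porosity_nodes(params)
    ewe, epe = dl.effective_component_eps(phi, freq, params)
    lam = dl.local_percolation_probability(phi, params)
    c = None
    for _ in range(n_levels):
        re = np.linspace(re_lo, re_hi, grid)
        im = np.linspace(im_lo, im_hi, grid)
        RE, IM = np.meshgrid(re, im)
        E = RE - 1j * IM
        dw = ewe[None, None, :] + 2 * E[..., None]
        dp = epe[None, None, :] + 2 * E[..., None]
        F = (mu_w * (lam * (ewe - E[..., None]) / dw
                     + (1 - lam) * (epe - E[..., None]) / dp)).sum(-1)
        k = np.unravel_index(np.argmin(np.abs(F)), F.shape)
        c = E[k]
        dre, dim = re[1] - re[0], im[1] - im[0]
        re_lo, re_hi = c.real - 2 * dre, c.real + 2 * dre
        im_lo, im_hi = max(-c.imag - 2 * dim, 0.0), -c.imag + 2 * dim
    return c
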