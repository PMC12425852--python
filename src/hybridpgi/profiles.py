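"""Parametric longitudinal emission profiles and the emission model.

The generator replaces full transport physics by parametric depth profiles
along the beam axis x (beam travels toward decreasing x).  A profile is the
sum of up to four components:

* a flat *plateau* between the phantom entrance and the Bragg peak
  (slowing-down region),
* a Gaussian *Bragg peak* (position, width),
* a Gaussian *entrance flash* — the intense prompt-gamma locus at the
  phantom entrance observed for He and C ions, absent for protons by
  default,
* an exponential *distal tail* beyond the peak (projectile fragments
  reaching past the Bragg peak for C ions).

Profiles are tabulated on a fine grid and sampled by inverse-CDF lookup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepthProfile",
    "IsotopeSpec",
    "EmissionModel",
    "default_isotopes",
    "graphite_55mev_model",
    "pe_155mev_model",
]

#: prompt-gamma line energies (keV) and default weights; the spectrum extends
#: to 5-6 MeV with a prominent 4.44 MeV carbon de-excitation line.
DEFAULT_PROMPT_LINES = ((718.0, 0.25), (2000.0, 0.30), (4440.0, 0.35),
                        (6130.0, 0.10))

#: 4 mm FWHM transverse beam spot at 155 MeV
DEFAULT_BEAM_SIGMA = 4.0 / 2.355


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class DepthProfile:
    """Non-negative intensity vs depth x (mm), beam toward decreasing x."""

    x_min: float
    x_max: float
    peak_position: float = 0.0
    peak_sigma: float = 3.0
    peak_amplitude: float = 1.0
    plateau_amplitude: float = 0.0
    plateau_range: tuple | None = None  # (x_lo, x_hi); default peak..entrance
    #: Gaussian smearing of the plateau's deep boundary (erfc fall-off);
    #: 0 keeps a sharp step
    edge_sigma: float = 0.0
    flash_position: float | None = None
    flash_sigma: float = 5.0
    flash_amplitude: float = 0.0
    tail_amplitude: float = 0.0
    tail_scale: float = 10.0
    n_grid: int = 4000

    def __post_init__(self):
        if not self.x_min < self.x_max:
            raise ModelError("x_min must be < x_max")
        if self.peak_sigma < 0 or self.flash_sigma <= 0 or self.tail_scale <= 0:
            raise ModelError("profile widths must be positive")
        if min(self.peak_amplitude, self.plateau_amplitude,
               self.flash_amplitude, self.tail_amplitude) < 0:
            raise ModelError("profile amplitudes must be non-negative")

    def shifted(self, dx: float) -> "DepthProfile":
        """Profile translated by dx along the beam axis."""
        from dataclasses import replace
        kw = dict(x_min=self.x_min + dx, x_max=self.x_max + dx,
                  peak_position=self.peak_position + dx)
        if self.plateau_range is not None:
            kw["plateau_range"] = (self.plateau_range[0] + dx,
                                   self.plateau_range[1] + dx)
        if self.flash_position is not None:
            kw["flash_position"] = self.flash_position + dx
        return replace(self, **kw)

    def intensity(self, x) -> np.ndarray:
        """Unnormalized intensity; vectorized in x."""
        x = np.asarray(x, dtype=float)
        v = np.zeros_like(x)
        if self.peak_amplitude > 0:
            if self.peak_sigma == 0:
                v = v + np.where(x == self.peak_position,
                                 self.peak_amplitude, 0.0)
            else:
                v = v + self.peak_amplitude * np.exp(
                    -0.5 * ((x - self.peak_position) / self.peak_sigma) ** 2)
        if self.plateau_amplitude > 0:
            lo, hi = (self.plateau_range if self.plateau_range is not None
                      else (self.peak_position, self.x_max))
            if self.edge_sigma > 0:
                from scipy import special
                # deep boundary smeared into an erfc fall-off (beam -> -x)
                rise = 0.5 * special.erfc(
                    (lo - x) / (np.sqrt(2.0) * self.edge_sigma))
                v = v + self.plateau_amplitude * rise * (x <= hi)
            else:
                v = v + np.where((x >= lo) & (x <= hi),
                                 self.plateau_amplitude, 0.0)
        if self.flash_amplitude > 0 and self.flash_position is not None:
            v = v + self.flash_amplitude * np.exp(
                -0.5 * ((x - self.flash_position) / self.flash_sigma) ** 2)
        if self.tail_amplitude > 0:
            # beam toward -x: the tail extends to depths beyond (below) the peak
            d = self.peak_position - x
            v = v + np.where(d > 0,
                             self.tail_amplitude * np.exp(-d / self.tail_scale),
                             0.0)
        return v

    def _grid_cdf(self):
        xg = np.linspace(self.x_min, self.x_max, self.n_grid)
        pdf = self.intensity(xg)
        total = np.trapezoid(pdf, xg)
        if total <= 0:
            raise ModelError("profile has zero total intensity")
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (pdf[1:] + pdf[:-1]) * np.diff(xg))])
        return xg, cdf / cdf[-1]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n depths by inverse-CDF lookup on the tabulated profile."""
        if self.peak_sigma == 0 and self.plateau_amplitude == 0 \
                and self.flash_amplitude == 0 and self.tail_amplitude == 0:
            return np.full(n, self.peak_position)  # point-source limit
        xg, cdf = self._grid_cdf()
        u = rng.random(n)
        return np.interp(u, cdf, xg)


@dataclass(frozen=True)
class IsotopeSpec:
    """A beta+ emitter: name, half-life (ms), production depth profile, yield."""

    name: str
    half_life_ms: float
    production_profile: DepthProfile
    yield_weight: float = 1.0

    def __post_init__(self):
        if self.half_life_ms <= 0:
            raise ModelError("half_life must be > 0")
        if self.yield_weight < 0:
            raise ModelError("yield must be >= 0")

    @property
    def lam_per_s(self) -> float:
        """Decay constant lambda = ln2 / T_1/2, in 1/s."""
        return np.log(2.0) / (self.half_life_ms * 1e-3)


#: half-lives treated as fixed physics: 9C 126.5 ms, 12N 10 ms, 13O 8 ms;
#: long-lived set 10C 19.3 s, 15O 122.4 s, 11C 20.4 min
HALF_LIVES_MS = {"9C": 126.5, "12N": 10.0, "13O": 8.0,
                 "10C": 19.3e3, "15O": 122.4e3, "11C": 20.4 * 60e3}


def default_isotopes(profile: DepthProfile,
                     yields: dict | None = None) -> tuple:
    """Default beta+ emitter set sharing one production profile.

    Short-lived species dominate the off-spill signal under the 45/255 ms
    duty cycle; default yields favour 9C as the simulations in this setting
    indicate, with a long-lived floor.
    """
    y = {"9C": 1.0, "12N": 0.3, "13O": 0.2, "10C": 0.5, "15O": 0.3, "11C": 0.3}
    if yields:
        y = dict(yields)
    return tuple(IsotopeSpec(k, HALF_LIVES_MS[k], profile, w)
                 for k, w in y.items() if w > 0)


@dataclass(frozen=True)
class EmissionModel:
    prompt_profile: DepthProfile
    isotopes: tuple
    prompt_lines: tuple = DEFAULT_PROMPT_LINES
    positron_range_sigma: float = 2.0
    beam_sigma_transverse: float = DEFAULT_BEAM_SIGMA

    def __post_init__(self):
        w = sum(wt for _, wt in self.prompt_lines)
        if not np.isclose(w, 1.0):
            raise ModelError(f"prompt line weights must sum to 1 (got {w})")
        if self.positron_range_sigma < 0:
            raise ModelError("positron_range_sigma must be >= 0")


def graphite_55mev_model(position: float = 0.0,
                         yields: dict | None = None) -> EmissionModel:
    """55 MeV protons on the graphite cylinder at ``position`` (mm).

    Proton range in graphite at 55 MeV is ~20 mm: the Bragg peak sits near
    the cylinder center when the beam enters the upstream face; both the
    prompt and activation loci are narrow and nearly coincident, which is
    what makes the three modalities directly comparable at this energy.
    No entrance flash for protons.
    """
    prompt = DepthProfile(
        x_min=position - 30.0, x_max=position + 30.0,
        peak_position=position, peak_sigma=3.0, peak_amplitude=1.0,
        plateau_amplitude=0.15, plateau_range=(position, position + 25.0))
    beta = DepthProfile(
        x_min=position - 30.0, x_max=position + 30.0,
        peak_position=position - 1.0, peak_sigma=4.0, peak_amplitude=1.0,
        plateau_amplitude=0.10, plateau_range=(position - 1.0, position + 25.0))
    return EmissionModel(prompt, default_isotopes(beta, yields))


def pe_155mev_model(shift: float = 0.0, species: str = "p",
                    yields: dict | None = None) -> EmissionModel:
    """155 MeV p/He (or 275 MeV C) on the 180 mm PE block, shifted by ``shift``.

    The block is mounted upstream-shifted (center x = -20 mm, entrance face
    at +70 mm) with the beam range ending deep inside it.  At desk scale the
    Bragg peak is placed centered in the field of view of the downstream
    imager pair (x ~ -55 mm) so the distal fall-off stays within the span
    the four-imager setup can reconstruct; the beta+ edge lies a few mm
    deeper.  He and C ions add a strong gamma-flash component at the
    entrance that masks the Bragg-peak photons.
    """
    flash_amp = 0.0 if species == "p" else 3.0
    prompt = DepthProfile(
        x_min=-100.0, x_max=75.0,
        peak_position=-55.0, peak_sigma=6.0, peak_amplitude=1.0,
        plateau_amplitude=0.25, plateau_range=(-55.0, 68.0),
        flash_position=65.0, flash_sigma=8.0, flash_amplitude=flash_amp,
        tail_amplitude=0.05 if species == "C" else 0.0, tail_scale=15.0)
    # the off-spill beta+ activity at this energy is a broad plateau over
    # the track with a Gaussian-smeared fall-off near range end, not a
    # narrow peak; the erfc midpoint sits a few mm short of the Bragg peak
    beta = DepthProfile(
        x_min=-100.0, x_max=75.0,
        peak_position=-60.0, peak_sigma=8.0, peak_amplitude=0.0,
        plateau_amplitude=1.0, plateau_range=(-62.0, 68.0), edge_sigma=4.0,
        tail_amplitude=0.05 if species == "C" else 0.0, tail_scale=15.0)
    model = EmissionModel(prompt.shifted(shift),
                          default_isotopes(beta.shifted(shift), yields))
    return model
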