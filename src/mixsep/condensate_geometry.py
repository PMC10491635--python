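"""Condensate identification, radial density profiles and interface fits.

The condensate is the largest connected component of the chain contact
graph (chains are linked when any inter-chain bead pair lies within the
26-site neighborhood).  Densities are binned into radial shells of 0.25
lattice units around the condensate center of mass, normalized by the exact
number of lattice sites per shell (the exact prior for a cubic lattice of
the given size), so that a shell's value is a volume fraction.  A
4-parameter logistic fit of the radial density yields the dense and dilute
levels, the interface midpoint r0 and the steepness w; the interfacial
region is taken as the logistic 10-90% band, [r0 - w ln 9, r0 + w ln 9].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit

from .lattice_engine import LatticeState, _OFFS

__all__ = [
    "SHELL_WIDTH",
    "CondensateResult",
    "RadialProfile",
    "LogisticFit",
    "RgProfile",
    "find_condensate",
    "chain_contact_graph",
    "radial_density",
    "logistic",
    "fit_logistic",
    "phase_concentrations",
    "rg_profile",
    "unwrap_chain",
    "chain_rg",
]

SHELL_WIDTH = 0.25  # lattice units

LN9 = math.log(9.0)


# ---------------------------------------------------------------------------
# condensate identification
# ---------------------------------------------------------------------------

def chain_contact_graph(state: LatticeState) -> nx.Graph:
    """Graph over chain indices; edge when any inter-chain bead pair is a
    26-neighborhood contact."""
    sys_ = state.system
    L = sys_.L
    g = nx.Graph()
    g.add_nodes_from(range(sys_.n_chains))
    occ = state.occ
    pos = state.positions
    chain_of_bead = sys_.chain_of_bead
    for b in range(sys_.n_beads):
        cb = chain_of_bead[b]
        x, y, z = pos[b]
        for k in range(26):
            q = occ[(x + _OFFS[k, 0]) % L, (y + _OFFS[k, 1]) % L,
                    (z + _OFFS[k, 2]) % L]
            if q > b and chain_of_bead[q] != cb:
                g.add_edge(int(cb), int(chain_of_bead[q]))
    return g


def periodic_center(points: np.ndarray, L: int) -> np.ndarray:
    """Periodic (circular-mean) centroid of integer points, per axis."""
    theta = points * (2 * np.pi / L)
    mean = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return (mean * L / (2 * np.pi)) % L


@dataclass
class CondensateResult:
    chains: tuple[int, ...]
    center: np.ndarray
    is_condensate: bool
    fraction_of_chains: float


def find_condensate(
    state: LatticeState, min_fraction: float = 0.5
) -> CondensateResult:
    """Largest connected chain cluster and its periodic center of mass.

    A fully dispersed system still returns its largest (possibly
    single-chain) component, flagged ``is_condensate=False`` when it holds
    fewer than ``min_fraction`` of all chains.  Ties between equally large
    components break toward the one containing the lowest chain index.
    """
    sys_ = state.system
    g = chain_contact_graph(state)
    components = sorted(
        nx.connected_components(g), key=lambda comp: (-len(comp), min(comp))
    )
    chains = tuple(sorted(components[0]))
    beads = np.concatenate([
        state.chain_positions(c) for c in chains
    ])
    center = periodic_center(beads, sys_.L)
    frac = len(chains) / sys_.n_chains
    return CondensateResult(
        chains=chains,
        center=center,
        is_condensate=frac >= min_fraction,
        fraction_of_chains=frac,
    )


# ---------------------------------------------------------------------------
# radial density with exact lattice shell priors
# ---------------------------------------------------------------------------

def _site_distances(L: int, center: np.ndarray) -> np.ndarray:
    ax = np.arange(L, dtype=float)
    d = []
    for axis in range(3):
        dd = (ax - center[axis] + L / 2) % L - L / 2
        d.append(dd**2)
    return np.sqrt(
        d[0][:, None, None] + d[1][None, :, None] + d[2][None, None, :]
    )


@dataclass
class RadialProfile:
    """Per-species shell volume fractions around a condensate center."""

    edges: np.ndarray  # (n_shells + 1,) in lattice units, spacing 0.25
    site_counts: np.ndarray  # exact lattice sites per shell; sums to L^3
    bead_counts: dict[str, np.ndarray]  # per-species beads per shell
    L: int
    center: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_shells(self) -> int:
        return len(self.site_counts)

    def density(self, species: str | None = None) -> np.ndarray:
        """Shell volume fraction (beads per site); NaN where a shell holds
        no lattice sites.  ``species=None`` sums over all species."""
        if species is None:
            counts = sum(self.bead_counts.values())
        else:
            counts = self.bead_counts[species]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.site_counts > 0, counts / self.site_counts, np.nan
            )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.bead_counts)

    def to_frame(self):
        import pandas as pd

        data = {
            "shell_center": self.centers,
            "site_count": self.site_counts,
        }
        for name in self.bead_counts:
            data[f"beads_{name}"] = self.bead_counts[name]
            data[f"density_{name}"] = self.density(name)
        data["density_total"] = self.density()
        return pd.DataFrame(data)


def mean_profile(profiles: list[RadialProfile]) -> RadialProfile:
    """Average radial profiles over frames/replicates, shell by shell.

    Centers may differ between frames; profiles are aligned on the common
    0.25-unit shell grid and bead/site counts are summed, so the resulting
    densities are site-weighted means.  Useful to smooth single-snapshot
    noise before interface fitting.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    n = max(p.n_shells for p in profiles)

    def pad(a, fill=0):
        out = np.full(n, fill, dtype=float)
        out[: len(a)] = a
        return out

    site = np.sum([pad(p.site_counts) for p in profiles], axis=0)
    species = profiles[0].species
    beads = {
        name: np.sum([pad(p.bead_counts[name]) for p in profiles], axis=0)
        for name in species
    }
    return RadialProfile(
        edges=np.arange(n + 1) * SHELL_WIDTH,
        site_counts=site,
        bead_counts=beads,
        L=profiles[0].L,
        center=profiles[0].center,
    )


def radial_density(
    state: LatticeState, center: np.ndarray, species: str | None = None
) -> RadialProfile:
    """Radial shell volume fractions with 0.25-lattice-unit shells.

    Sites are assigned to shells by their exact minimum-image distance to
    the (possibly fractional) center; each shell's density is the bead
    count divided by the exact site count, so uniform occupancy yields a
    flat profile at the global volume fraction.  All species are binned;
    ``species`` restricts the returned profile's bead_counts to one name.
    """
    sys_ = state.system
    L = sys_.L
    center = np.asarray(center, dtype=float)
    dist = _site_distances(L, center)
    r_max = dist.max()
    n_shells = int(math.floor(r_max / SHELL_WIDTH)) + 1
    edges = np.arange(n_shells + 1) * SHELL_WIDTH
    shell_of_site = np.minimum(
        (dist / SHELL_WIDTH).astype(np.int64), n_shells - 1
    )
    site_counts = np.bincount(shell_of_site.ravel(), minlength=n_shells)
    names = sys_.species_names
    wanted = names if species is None else (species,)
    bead_counts: dict[str, np.ndarray] = {}
    species_of_bead = sys_.species_of_chain[sys_.chain_of_bead]
    pos = state.positions
    bead_shells = shell_of_site[pos[:, 0], pos[:, 1], pos[:, 2]]
    for si, name in enumerate(names):
        if name not in wanted:
            continue
        mask = species_of_bead == si
        bead_counts[name] = np.bincount(
            bead_shells[mask], minlength=n_shells
        )
    return RadialProfile(
        edges=edges,
        site_counts=site_counts,
        bead_counts=bead_counts,
        L=L,
        center=center,
    )


# ---------------------------------------------------------------------------
# logistic interface fit
# ---------------------------------------------------------------------------

def logistic(r, rho_den, rho_dil, r0, w):
    """rho(r) = rho_dil + (rho_den - rho_dil) / (1 + exp((r - r0)/w))."""
    z = np.clip((np.asarray(r, dtype=float) - r0) / w, -700.0, 700.0)
    return rho_dil + (rho_den - rho_dil) / (1.0 + np.exp(z))


@dataclass
class LogisticFit:
    rho_dense: float
    rho_dilute: float
    r0: float
    w: float
    cov: np.ndarray | None = None
    residual: float = np.nan
    flagged: bool = False
    message: str = ""
    species: str | None = None

    @property
    def interface_lo(self) -> float:
        """Inner edge of the 10-90% interfacial band: r0 - w ln 9."""
        return self.r0 - self.w * LN9

    @property
    def interface_hi(self) -> float:
        """Outer edge of the 10-90% interfacial band: r0 + w ln 9."""
        return self.r0 + self.w * LN9

    @property
    def interface_width(self) -> float:
        return 2.0 * self.w * LN9


def fit_logistic(
    profile: RadialProfile,
    species: str | None = None,
    r_max: float | None = None,
) -> LogisticFit:
    """Least-squares logistic fit of a radial density profile.

    Initialization: dense level from the maximum shell density, dilute
    level from the mean of the outer 20% of shells, midpoint from the
    half-maximum radius, steepness 0.5 lattice units.  Bounds keep the
    levels nonnegative and w in (0, L/2).  Shells are weighted by their
    exact site counts (sigma ~ 1/sqrt(sites)), so the innermost shells,
    which hold only a handful of lattice sites, cannot dominate the fit.
    Non-convergence or a degenerate (flat) profile returns a flagged fit,
    never a silent fallback.
    """
    r = profile.centers
    rho = profile.density(species)
    keep = ~np.isnan(rho)
    if r_max is None:
        r_max = profile.L / 2 * math.sqrt(3.0)
    keep &= r <= r_max
    sigma = 1.0 / np.sqrt(np.maximum(profile.site_counts[keep], 1))
    r, rho = r[keep], rho[keep]
    if len(r) < 8:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, flagged=True,
                           message="fewer than 8 shells with defined density",
                           species=species)
    rho_den0 = float(rho.max())
    n_outer = max(1, int(0.2 * len(rho)))
    rho_dil0 = float(rho[-n_outer:].mean())
    if rho_den0 - rho_dil0 < 1e-12 or np.ptp(rho) < 1e-12:
        return LogisticFit(rho_den0, rho_dil0, np.nan, np.nan, flagged=True,
                           message="flat profile: interface unidentifiable",
                           species=species)
    half = rho_dil0 + 0.5 * (rho_den0 - rho_dil0)
    below = np.nonzero(rho < half)[0]
    r0_0 = float(r[below[0]]) if len(below) else float(r[len(r) // 2])
    bounds = ([0.0, 0.0, 0.0, 1e-6], [1.0, 1.0, r.max(), profile.L / 2])
    p0 = [rho_den0, rho_dil0, r0_0, 2 * SHELL_WIDTH]
    p0 = [min(max(v, lo), hi) for v, lo, hi in zip(p0, *bounds)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                logistic, r, rho, p0=p0, bounds=bounds, sigma=sigma,
                maxfev=20000
            )
    except (RuntimeError, ValueError) as exc:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, flagged=True,
                           message=f"fit failed: {exc}", species=species)
    resid = float(np.sqrt(np.mean((logistic(r, *popt) - rho) ** 2)))
    fit = LogisticFit(
        rho_dense=float(popt[0]),
        rho_dilute=float(popt[1]),
        r0=float(popt[2]),
        w=float(popt[3]),
        cov=pcov,
        residual=resid,
        species=species,
    )
    if fit.rho_dense < fit.rho_dilute:
        fit.flagged = True
        fit.message = "fitted dense level below dilute level"
    return fit


def phase_concentrations(
    profile: RadialProfile, fit: LogisticFit, species: str
) -> tuple[float, float]:
    """(c_dilute, c_dense) volume fractions for one species.

    c_dense averages the species volume fraction over shells interior to
    the fitted interface (r < r0 - w ln 9, site-weighted).  c_dilute is the
    species bead count in the whole exterior region (r > r0 + w ln 9)
    divided by the exact exterior site count, so dispersed chains far from
    the condensate are counted.
    """
    if fit.flagged:
        raise ValueError(f"cannot derive concentrations from a flagged fit: "
                         f"{fit.message}")
    inner = profile.edges[1:] <= fit.interface_lo
    outer = profile.edges[:-1] >= fit.interface_hi
    inner_sites = profile.site_counts[inner].sum()
    outer_sites = profile.site_counts[outer].sum()
    if inner_sites == 0 or outer_sites == 0:
        raise ValueError(
            "interface region covers the whole box: no two-phase coexistence"
        )
    counts = profile.bead_counts[species]
    c_dense = counts[inner].sum() / inner_sites
    c_dilute = counts[outer].sum() / outer_sites
    return float(c_dilute), float(c_dense)


# ---------------------------------------------------------------------------
# chain-dimension profiles
# ---------------------------------------------------------------------------

def unwrap_chain(points: np.ndarray, L: int) -> np.ndarray:
    """Unwrap periodic chain coordinates by cumulating minimum-image bonds.

    Bonds never exceed the 26-neighborhood, so unwrapping along the chain
    is exact.
    """
    steps = (points[1:] - points[:-1] + L // 2) % L - L // 2
    out = np.empty_like(points)
    out[0] = points[0]
    out[1:] = points[0] + np.cumsum(steps, axis=0)
    return out


def chain_rg(points: np.ndarray, L: int) -> float:
    """Radius of gyration of one chain on unwrapped coordinates."""
    u = unwrap_chain(np.asarray(points, dtype=np.int64), L).astype(float)
    return float(np.sqrt(((u - u.mean(axis=0)) ** 2).sum(axis=1).mean()))


@dataclass
class RgProfile:
    """Bead-weighted shell means of Rg/sqrt(N) per species."""

    centers: np.ndarray
    values: dict[str, np.ndarray]  # NaN below min bead count
    weights: dict[str, np.ndarray]  # bead counts per shell
    min_beads: int


def rg_profile(
    state: LatticeState, center: np.ndarray, min_beads: int = 10
) -> RgProfile:
    """Radial profile of Rg/sqrt(N), binning each bead independently.

    Every bead contributes its chain's Rg/sqrt(N) to the bead's own radial
    shell, and the shell value is the bead-weighted mean; a single chain
    can therefore span (and contribute to) multiple shells.  Shells with
    fewer than ``min_beads`` contributing beads are undefined (NaN).
    """
    sys_ = state.system
    L = sys_.L
    center = np.asarray(center, dtype=float)
    d = (state.positions - center + L / 2) % L - L / 2
    r = np.sqrt((d**2).sum(axis=1))
    n_shells = int(math.floor(r.max() / SHELL_WIDTH)) + 1
    shell = np.minimum((r / SHELL_WIDTH).astype(np.int64), n_shells - 1)
    rg_per_chain = np.array([
        chain_rg(state.chain_positions(c), L) for c in range(sys_.n_chains)
    ])
    n_per_chain = np.diff(sys_.chain_starts)
    norm = rg_per_chain / np.sqrt(n_per_chain)
    bead_value = norm[sys_.chain_of_bead]
    species_of_bead = sys_.species_of_chain[sys_.chain_of_bead]
    values: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    for si, name in enumerate(sys_.species_names):
        mask = species_of_bead == si
        w = np.bincount(shell[mask], minlength=n_shells).astype(float)
        s = np.bincount(shell[mask], weights=bead_value[mask],
                        minlength=n_shells)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(w >= min_beads, s / np.maximum(w, 1), np.nan)
        values[name] = v
        weights[name] = w
    centers = (np.arange(n_shells) + 0.5) * SHELL_WIDTH
    return RgProfile(centers=centers, values=values, weights=weights,
                     min_beads=min_beads)
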