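"""Molecular species and their interaction energetics.

A chain is represented at one bead per residue.  Species are described by a
:class:`ChainSpec` (sequence, length, net charge per residue, fraction of
charged residues).  Pairwise bead-bead contact energies combine an isotropic
term, an optional anisotropic term, and a mean-field electrostatic term that
depends on the net charge per residue (NCPR) of the chains the two beads
belong to.  For a mixture, the electrostatic term uses the average NCPR of
the two chains, which reduces to the single-species rule when both beads
belong to chains of the same species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "COMPOSITION_CATEGORIES",
    "AlphabetError",
    "ChainSpec",
    "CompositionProfile",
    "InteractionTable",
    "compute_charge_descriptors",
    "composition_profile",
    "pair_contact_energy",
    "make_charge_variant",
    "read_fasta",
    "electrostatic_forms",
    "mass_to_molecule_ratio",
    "molecule_to_mass_ratio",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

CATIONIC = frozenset("KR")
ANIONIC = frozenset("DE")
CHARGED = CATIONIC | ANIONIC

#: Residue category memberships used for composition profiles.  The six
#: categories are disjoint and exhaustive over the 20 amino acids.
COMPOSITION_CATEGORIES: dict[str, frozenset[str]] = {
    "polar": frozenset("GSTNQC"),
    "aromatic": frozenset("FYWH"),
    "hydrophobic": frozenset("LIVM"),
    "charged": frozenset("DERK"),
    "proline": frozenset("P"),
    "other": frozenset("A"),
}


class AlphabetError(ValueError):
    """Raised when a residue code is not part of the working alphabet."""


def _check_residues(residues: Sequence[str], alphabet: Iterable[str] = AMINO_ACIDS) -> None:
    allowed = set(alphabet)
    for code in residues:
        if code not in allowed:
            raise AlphabetError(f"unknown residue code {code!r}")


def compute_charge_descriptors(residues: Sequence[str]) -> tuple[float, float]:
    """Return ``(ncpr, fcr)`` for a residue sequence.

    NCPR is (count{K,R} - count{D,E}) / N and FCR is count{K,R,D,E} / N.
    Both are invariant under permutation of the sequence.
    """
    if len(residues) == 0:
        raise ValueError("empty residue sequence")
    _check_residues(residues)
    n = len(residues)
    pos = sum(1 for r in residues if r in CATIONIC)
    neg = sum(1 for r in residues if r in ANIONIC)
    return (pos - neg) / n, (pos + neg) / n


@dataclass(frozen=True)
class CompositionProfile:
    """Fractions of residues per composition category.

    Categories: polar (G,S,T,N,Q,C), aromatic (F,Y,W,H), hydrophobic
    (L,I,V,M), charged (D,E,R,K), proline, other (A).  Fractions sum to 1.
    """

    polar: float
    aromatic: float
    hydrophobic: float
    charged: float
    proline: float
    other: float

    def __post_init__(self) -> None:
        total = sum(self.as_dict().values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"category fractions sum to {total}, expected 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "polar": self.polar,
            "aromatic": self.aromatic,
            "hydrophobic": self.hydrophobic,
            "charged": self.charged,
            "proline": self.proline,
            "other": self.other,
        }


def composition_profile(residues: Sequence[str]) -> CompositionProfile:
    """Compute the category composition profile of a sequence."""
    if len(residues) == 0:
        raise ValueError("empty residue sequence")
    _check_residues(residues)
    n = len(residues)
    counts = {name: 0 for name in COMPOSITION_CATEGORIES}
    for r in residues:
        for name, members in COMPOSITION_CATEGORIES.items():
            if r in members:
                counts[name] += 1
                break
    return CompositionProfile(**{name: counts[name] / n for name in counts})


@dataclass(frozen=True)
class ChainSpec:
    """Identity card of a molecular species.

    ``residues`` holds one-letter codes; homopolymer proxies use a single
    synthetic code per species and carry explicitly configured charge
    descriptors (zero by default).
    """

    name: str
    residues: tuple[str, ...]
    length: int
    ncpr: float
    fcr: float

    def __post_init__(self) -> None:
        if self.length != len(self.residues):
            raise ValueError("length must equal the number of residues")
        if self.length < 1:
            raise ValueError("chain must have at least one bead")
        if not (abs(self.ncpr) <= self.fcr + 1e-12 and self.fcr <= 1 + 1e-12):
            raise ValueError(f"require |ncpr| <= fcr <= 1, got {self.ncpr}, {self.fcr}")

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "ChainSpec":
        """Build a spec from an amino-acid sequence; descriptors computed."""
        residues = tuple(sequence.upper())
        ncpr, fcr = compute_charge_descriptors(residues)
        return cls(name=name, residues=residues, length=len(residues), ncpr=ncpr, fcr=fcr)

    @classmethod
    def homopolymer(
        cls, name: str, code: str, length: int, ncpr: float = 0.0, fcr: float = 0.0
    ) -> "ChainSpec":
        """A homopolymer species with a single (possibly synthetic) bead code."""
        if len(code) != 1:
            raise ValueError("homopolymer code must be a single character")
        return cls(name=name, residues=(code,) * length, length=length, ncpr=ncpr, fcr=fcr)

    @property
    def composition(self) -> CompositionProfile:
        return composition_profile(self.residues)


def make_charge_variant(
    spec: ChainSpec,
    n_substitutions: int,
    target_residue: str,
    replaceable: Iterable[str],
    seed: int = 0,
) -> ChainSpec:
    """Substitute ``n_substitutions`` replaceable residues with a target residue.

    Positions are drawn uniformly along the sequence (without replacement),
    deterministically for a given seed.  Charge descriptors are recomputed;
    the length is unchanged.  Mirrors the construction of charge variants in
    which a number of spacer residues are swapped for aspartate.
    """
    if n_substitutions < 0:
        raise ValueError("n_substitutions must be nonnegative")
    replaceable = set(replaceable)
    candidates = [i for i, r in enumerate(spec.residues) if r in replaceable]
    if len(candidates) < n_substitutions:
        raise ValueError(
            f"only {len(candidates)} replaceable residues available, "
            f"need {n_substitutions}"
        )
    if n_substitutions == 0:
        return spec
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_substitutions, replace=False)
    positions = {candidates[int(i)] for i in chosen}
    residues = tuple(
        target_residue if i in positions else r for i, r in enumerate(spec.residues)
    )
    ncpr, fcr = compute_charge_descriptors(residues)
    return ChainSpec(
        name=f"{spec.name}+{n_substitutions}{target_residue}",
        residues=residues,
        length=spec.length,
        ncpr=ncpr,
        fcr=fcr,
    )


# --------------------------------------------------------------------------
# Interaction energetics
# --------------------------------------------------------------------------

def _mean_ncpr_squared(ncpr_i: float, ncpr_j: float, lambda_el: float) -> float:
    """Like-charge mean-field penalty: lambda_el * ((n_i + n_j)/2)**2.

    Nonnegative; vanishes when the two chains' charges balance, so
    oppositely charged chain pairs pay no electrostatic penalty while
    like-charged pairs do.  For a single-component system it reduces to
    lambda_el * ncpr**2.
    """
    nbar = 0.5 * (ncpr_i + ncpr_j)
    return lambda_el * nbar * nbar


#: Registry of pluggable electrostatic forms, keyed by name.
electrostatic_forms: dict[str, Callable[[float, float, float], float]] = {
    "mean_ncpr_squared": _mean_ncpr_squared,
}


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric residue-pair contact energies in reduced units.

    ``iso`` and ``aniso`` are square matrices over ``alphabet`` (negative
    values are attractive).  ``lambda_el`` couples the mean-field
    electrostatic term; ``electrostatic_form`` names the functional form in
    :data:`electrostatic_forms`.
    """

    alphabet: tuple[str, ...]
    iso: np.ndarray
    aniso: np.ndarray
    lambda_el: float = 0.0
    electrostatic_form: str = "mean_ncpr_squared"

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        iso = np.asarray(self.iso, dtype=float)
        aniso = np.asarray(self.aniso, dtype=float)
        object.__setattr__(self, "iso", iso)
        object.__setattr__(self, "aniso", aniso)
        if iso.shape != (k, k) or aniso.shape != (k, k):
            raise ValueError("iso/aniso must be square over the alphabet")
        if not (np.allclose(iso, iso.T) and np.allclose(aniso, aniso.T)):
            raise ValueError("iso and aniso must be symmetric")
        if not (np.isfinite(iso).all() and np.isfinite(aniso).all()):
            raise ValueError("energies must be finite")
        if self.lambda_el < 0:
            raise ValueError("lambda_el must be nonnegative")
        if self.electrostatic_form not in electrostatic_forms:
            raise ValueError(f"unknown electrostatic form {self.electrostatic_form!r}")

    def index(self, residue: str) -> int:
        try:
            return self.alphabet.index(residue)
        except ValueError:
            raise AlphabetError(
                f"residue {residue!r} not in interaction table alphabet"
            ) from None

    @classmethod
    def uniform(
        cls,
        alphabet: Iterable[str],
        iso_energy: float,
        aniso_energy: float = 0.0,
        lambda_el: float = 0.0,
    ) -> "InteractionTable":
        """All residue pairs share one isotropic (and anisotropic) energy."""
        alphabet = tuple(alphabet)
        k = len(alphabet)
        return cls(
            alphabet=alphabet,
            iso=np.full((k, k), float(iso_energy)),
            aniso=np.full((k, k), float(aniso_energy)),
            lambda_el=lambda_el,
        )

    @classmethod
    def from_species_energies(
        cls,
        pair_energies: Mapping[tuple[str, str], float],
        lambda_el: float = 0.0,
    ) -> "InteractionTable":
        """Build a table from species-level pair energies.

        Used for homopolymer systems where each species maps to a single
        bead code and only species-pair isotropic energies are specified
        (anisotropic energies zero).
        """
        codes = sorted({c for pair in pair_energies for c in pair})
        k = len(codes)
        iso = np.zeros((k, k))
        seen = np.zeros((k, k), dtype=bool)
        for (a, b), e in pair_energies.items():
            i, j = codes.index(a), codes.index(b)
            iso[i, j] = iso[j, i] = float(e)
            seen[i, j] = seen[j, i] = True
        if not seen.all():
            missing = [
                (codes[i], codes[j])
                for i in range(k)
                for j in range(i, k)
                if not seen[i, j]
            ]
            raise ValueError(f"missing species pair energies: {missing}")
        return cls(
            alphabet=tuple(codes), iso=iso, aniso=np.zeros((k, k)), lambda_el=lambda_el
        )

    # -- file round trip ---------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the table as CSV blocks with a key-value header line."""
        with open(path, "w") as fh:
            fh.write(f"# lambda_el={self.lambda_el!r}\n")
            fh.write(f"# electrostatic_form={self.electrostatic_form}\n")
            for label, mat in (("[iso]", self.iso), ("[aniso]", self.aniso)):
                fh.write(label + "\n")
                fh.write("," + ",".join(self.alphabet) + "\n")
                for code, row in zip(self.alphabet, mat):
                    fh.write(code + "," + ",".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_csv(cls, path) -> "InteractionTable":
        import pandas as pd

        lambda_el = 0.0
        form = "mean_ncpr_squared"
        blocks: dict[str, list[str]] = {}
        current: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#"):
                    key, _, value = line.lstrip("# ").partition("=")
                    if key.strip() == "lambda_el":
                        lambda_el = float(value)
                    elif key.strip() == "electrostatic_form":
                        form = value.strip()
                    continue
                if line.startswith("["):
                    current = blocks.setdefault(line.strip("[]").strip(), [])
                    continue
                if current is None:
                    raise ValueError("matrix rows before any [iso]/[aniso] block")
                current.append(line)
        if "iso" not in blocks:
            raise ValueError("interaction table file lacks an [iso] block")
        frames = {
            name: pd.read_csv(io.StringIO("\n".join(rows)), index_col=0)
            for name, rows in blocks.items()
        }
        alphabet = tuple(str(c) for c in frames["iso"].columns)
        iso = frames["iso"].to_numpy(dtype=float)
        if "aniso" in frames:
            aniso = frames["aniso"].loc[list(alphabet), list(alphabet)].to_numpy(dtype=float)
        else:
            aniso = np.zeros_like(iso)
        return cls(
            alphabet=alphabet,
            iso=iso,
            aniso=aniso,
            lambda_el=lambda_el,
            electrostatic_form=form,
        )


def pair_contact_energy(
    res_i: str,
    res_j: str,
    ncpr_chain_i: float,
    ncpr_chain_j: float,
    table: InteractionTable,
    anisotropic: bool = False,
) -> float:
    """Contact energy between two beads, in reduced units.

    Returns ``iso[res_i, res_j]`` (plus ``aniso[res_i, res_j]`` when the
    beads are anisotropically bonded) plus the electrostatic term evaluated
    on the NCPR values of the chains the beads belong to.  Symmetric under
    exchange of the two beads.
    """
    for n in (ncpr_chain_i, ncpr_chain_j):
        if not -1.0 <= n <= 1.0:
            raise ValueError(f"ncpr {n} outside [-1, 1]")
    i, j = table.index(res_i), table.index(res_j)
    e = float(table.iso[i, j])
    if anisotropic:
        e += float(table.aniso[i, j])
    form = electrostatic_forms[table.electrostatic_form]
    return e + form(ncpr_chain_i, ncpr_chain_j, table.lambda_el)


def mass_to_molecule_ratio(
    lengths: Sequence[int], mass_fractions: Sequence[float]
) -> tuple[float, ...]:
    """Convert mass fractions to molecule-number fractions.

    Bead count N stands in for molecular mass (one bead per residue), so a
    species' molecule count is proportional to its mass fraction divided by
    its length.  Simulations mix by molecule number while experiments mix
    by mass; this converts between the conventions explicitly, never
    implicitly.
    """
    if len(lengths) != len(mass_fractions):
        raise ValueError("lengths and mass fractions must align")
    if abs(sum(mass_fractions) - 1.0) > 1e-9:
        raise ValueError("mass fractions must sum to 1")
    mol = [m / n for m, n in zip(mass_fractions, lengths)]
    total = sum(mol)
    return tuple(x / total for x in mol)


def molecule_to_mass_ratio(
    lengths: Sequence[int], mol_fractions: Sequence[float]
) -> tuple[float, ...]:
    """Convert molecule-number fractions to mass (bead) fractions."""
    if len(lengths) != len(mol_fractions):
        raise ValueError("lengths and molecule fractions must align")
    if abs(sum(mol_fractions) - 1.0) > 1e-9:
        raise ValueError("molecule fractions must sum to 1")
    mass = [m * n for m, n in zip(mol_fractions, lengths)]
    total = sum(mass)
    return tuple(x / total for x in mass)


def read_fasta(path) -> list[ChainSpec]:
    """Read a multi-record FASTA into ChainSpecs (record id = species name)."""
    from Bio import SeqIO

    specs = [
        ChainSpec.from_sequence(record.id, str(record.seq))
        for record in SeqIO.parse(str(path), "fasta")
    ]
    if not specs:
        raise ValueError(f"no FASTA records found in {path}")
    return specs
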