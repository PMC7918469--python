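"""Species catalog, patch selectivity classes and mixture affinity matrices.

A protein is a hard sphere decorated with attractive surface patches
(binding sites).  The number, placement and strength of the patches set the
protein's effective valency; which patch pairs attract each other is
encoded in a symmetric :class:`InteractionMatrix` of well-depth multipliers
in units of the full well depth epsilon.  Four built-in six-component
mixture presets reproduce qualitatively different biological scenarios:
binding controlled purely by valency, preferential like-valency binding,
and two immiscible scaffolds without / with a shared client.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PatchClass",
    "SpeciesSpec",
    "InteractionMatrix",
    "MixtureSpec",
    "build_species_catalog",
    "build_mixture",
    "build_pure_system",
    "effective_valency",
    "MIXTURE_PRESETS",
    "SPECIES_NAMES",
    "mixture_to_dict",
    "mixture_from_dict",
    "save_mixture",
    "load_mixture",
]

_UNIT_TOL = 1e-10


@dataclass(frozen=True)
class PatchClass:
    """A selectivity class of binding site with an intrinsic strength in (0, 1]."""

    label: str
    intrinsic_strength: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.intrinsic_strength <= 1.0):
            raise ValueError(
                f"intrinsic_strength must be in (0, 1], got {self.intrinsic_strength}"
            )


@dataclass(frozen=True)
class SpeciesSpec:
    """A protein type: hard core plus body-frame patch directions and classes."""

    name: str
    patch_directions: tuple[tuple[float, float, float], ...]
    patch_classes: tuple[PatchClass, ...]

    def __post_init__(self) -> None:
        dirs = np.asarray(self.patch_directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError("patch_directions must be a list of 3-vectors")
        if len(self.patch_classes) != len(self.patch_directions):
            raise ValueError("one patch class per patch direction required")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("patch directions must be unit vectors")

    @property
    def n_patches(self) -> int:
        return len(self.patch_directions)

    @property
    def effective_valency(self) -> float:
        """Sum of intrinsic patch strengths (fractional for weakened sites)."""
        return float(sum(c.intrinsic_strength for c in self.patch_classes))

    @property
    def directions(self) -> np.ndarray:
        return np.asarray(self.patch_directions, dtype=float)

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.patch_classes)


class InteractionMatrix:
    """Symmetric patch-class x patch-class well-depth multipliers in [0, 1]."""

    def __init__(self, depths: Mapping[tuple[str, str], float]):
        self._depths: dict[tuple[str, str], float] = {}
        for (a, b), d in depths.items():
            d = float(d)
            if not (0.0 <= d <= 1.0):
                raise ValueError(f"depth for ({a}, {b}) outside [0, 1]: {d}")
            key = (a, b) if a <= b else (b, a)
            if key in self._depths and self._depths[key] != d:
                raise ValueError(f"conflicting entries for pair {key}")
            self._depths[key] = d

    def depth(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        try:
            return self._depths[key]
        except KeyError:
            raise KeyError(f"no interaction entry for patch-class pair {key}") from None

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self._depths

    @property
    def entries(self) -> dict[tuple[str, str], float]:
        return dict(self._depths)

    def labels(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._depths:
            out.add(a)
            out.add(b)
        return out


@dataclass(frozen=True)
class MixtureSpec:
    """A named composition (species, counts) plus its affinity matrix."""

    name: str
    composition: tuple[tuple[SpeciesSpec, int], ...]
    matrix: InteractionMatrix

    def __post_init__(self) -> None:
        for sp, count in self.composition:
            if count <= 0:
                raise ValueError(f"count for {sp.name} must be positive")
        labels = [c.label for sp, _ in self.composition for c in sp.patch_classes]
        for i, a in enumerate(labels):
            for b in labels[i:]:
                if (a, b) not in self.matrix:
                    raise ValueError(f"matrix does not cover patch-class pair ({a}, {b})")

    @property
    def species(self) -> tuple[SpeciesSpec, ...]:
        return tuple(sp for sp, _ in self.composition)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.composition)

    @property
    def n_particles(self) -> int:
        return sum(self.counts)

    def species_pair_enabled(self, name_a: str, name_b: str) -> bool:
        """True if any patch-class pair between the two species has depth > 0."""
        sp = {s.name: s for s in self.species}
        a, b = sp[name_a], sp[name_b]
        return any(
            self.matrix.depth(ca.label, cb.label) > 0.0
            for ca in a.patch_classes
            for cb in b.patch_classes
        )


# ---------------------------------------------------------------------------
# Built-in species catalog
# ---------------------------------------------------------------------------

SPECIES_NAMES = (
    "4v-promiscuous",
    "4v-selective",
    "3v-good",
    "3v-poor",
    "2.25v",
    "2v",
)

_S3 = np.sqrt(3.0)
_TETRAHEDRON = (
    (1 / _S3, 1 / _S3, 1 / _S3),
    (1 / _S3, -1 / _S3, -1 / _S3),
    (-1 / _S3, 1 / _S3, -1 / _S3),
    (-1 / _S3, -1 / _S3, 1 / _S3),
)
_TRIGONAL_PLANAR = (  # 120 degrees apart in the xy plane
    (1.0, 0.0, 0.0),
    (-0.5, _S3 / 2, 0.0),
    (-0.5, -_S3 / 2, 0.0),
)
_ORTHOGONAL = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
_POLAR = ((0.0, 0.0, 1.0), (0.0, 0.0, -1.0))

_WEAK_STRENGTH = 0.25  # the single weakened site of the 2.25-valency protein


def build_species_catalog() -> dict[str, SpeciesSpec]:
    """The six built-in multivalent protein types, keyed by name.

    Valencies decrease from 4 to 2: two tetrahedral 4-valency proteins (one
    promiscuous, one with two selective site types placed 2+2), a 3-valency
    protein with sterically favorable coplanar sites, a 3-valency protein
    with orthogonal (sterically poor) sites, a 2.25-valency variant of the
    good topology whose third site is weakened to strength 1/4, and a
    2-valency protein with two antiparallel (polar) sites.

    Patch-class labels are species-scoped so that selectivity rules can be
    conditioned on species identity in the affinity matrix.
    """
    p4 = PatchClass("4p")
    s4a, s4b = PatchClass("4sA"), PatchClass("4sB")
    g3 = PatchClass("3g")
    p3 = PatchClass("3p")
    full225, weak225 = PatchClass("2.25f"), PatchClass("2.25w", _WEAK_STRENGTH)
    v2 = PatchClass("2v")
    catalog = {
        "4v-promiscuous": SpeciesSpec("4v-promiscuous", _TETRAHEDRON, (p4,) * 4),
        "4v-selective": SpeciesSpec("4v-selective", _TETRAHEDRON, (s4a, s4a, s4b, s4b)),
        "3v-good": SpeciesSpec("3v-good", _TRIGONAL_PLANAR, (g3,) * 3),
        "3v-poor": SpeciesSpec("3v-poor", _ORTHOGONAL, (p3,) * 3),
        "2.25v": SpeciesSpec("2.25v", _TRIGONAL_PLANAR, (full225, full225, weak225)),
        "2v": SpeciesSpec("2v", _POLAR, (v2,) * 2),
    }
    assert tuple(catalog) == SPECIES_NAMES
    return catalog


# ---------------------------------------------------------------------------
# Mixture presets
# ---------------------------------------------------------------------------

MIXTURE_PRESETS = ("valency_driven", "like_valency", "non_competing", "competing")

_DEFAULT_CLIENT_PAIRING = {"4v-promiscuous": "2.25v", "4v-selective": "2v"}


def _combined_depth(ca: PatchClass, cb: PatchClass) -> float:
    """Lorentz-Berthelot (arithmetic-mean) combination of site strengths."""
    return 0.5 * (ca.intrinsic_strength + cb.intrinsic_strength)


def _species_pair_enabled(preset: str, a: SpeciesSpec, b: SpeciesSpec,
                          pairing: Mapping[str, str]) -> bool:
    if preset == "valency_driven":
        return True
    if preset == "like_valency":
        return abs(a.effective_valency - b.effective_valency) <= 1.0
    # non_competing / competing share a base rule set
    if a.name == b.name:
        return True
    names = {a.name, b.name}
    if names == {"4v-promiscuous", "4v-selective"}:
        return False
    for scaffold, client in pairing.items():
        if names == {scaffold, client}:
            return True
    if preset == "competing":
        if names in ({"4v-promiscuous", "3v-good"}, {"4v-selective", "3v-good"}):
            return True
    return False


def build_mixture(
    name: str,
    counts_per_species: int | Mapping[str, int] | None = None,
    client_pairing: Mapping[str, str] | None = None,
) -> MixtureSpec:
    """Build one of the four six-component mixture presets.

    Parameters
    ----------
    name
        One of ``valency_driven`` (every species pair attracts),
        ``like_valency`` (pairs attract iff their valencies differ by at
        most 1), ``non_competing`` (two mutually inert 4-valency scaffolds,
        each with a single dedicated low-valency client) or ``competing``
        (as non_competing, plus both scaffolds bind the 3-valency
        good-topology client).
    counts_per_species
        Particle count per species; a single int applies to every species.
        Defaults to 32 of each of the six types.
    client_pairing
        Scaffold -> client map for the non_competing/competing presets;
        defaults to promiscuous<->2.25-valency and selective<->2-valency.

    Notes
    -----
    Within the 4-valency selective species the two site types bind only to
    their own type (selective homotypic binding) but promiscuously to sites
    of other, enabled species.  Depths involving the weakened site of the
    2.25-valency protein follow the arithmetic-mean combination rule.
    """
    if name not in MIXTURE_PRESETS:
        raise ValueError(f"unknown mixture preset {name!r}; choose from {MIXTURE_PRESETS}")
    catalog = build_species_catalog()
    pairing = dict(_DEFAULT_CLIENT_PAIRING if client_pairing is None else client_pairing)

    if counts_per_species is None:
        counts_per_species = 32
    if isinstance(counts_per_species, int):
        counts = {nm: counts_per_species for nm in SPECIES_NAMES}
    else:
        counts = dict(counts_per_species)

    depths: dict[tuple[str, str], float] = {}
    species = list(catalog.values())
    for i, a in enumerate(species):
        for b in species[i:]:
            enabled = _species_pair_enabled(name, a, b, pairing)
            for ca in set(a.patch_classes):
                for cb in set(b.patch_classes):
                    if not enabled:
                        d = 0.0
                    elif a.name == b.name == "4v-selective" and ca.label != cb.label:
                        d = 0.0  # selective sites are inert to the other type on their parent
                    else:
                        d = _combined_depth(ca, cb)
                    key = tuple(sorted((ca.label, cb.label)))
                    depths[key] = d  # type: ignore[index]

    composition = tuple((catalog[nm], counts[nm]) for nm in SPECIES_NAMES)
    return MixtureSpec(name=name, composition=composition, matrix=InteractionMatrix(depths))


def build_pure_system(species_name: str, count: int = 192) -> MixtureSpec:
    """Single-species system with homotypic binding enabled.

    Depths follow the same rules as the presets: full-strength pairs at 1,
    combination rule for the weakened site, and the two selective site
    types of the 4-valency selective protein inert to each other.
    """
    catalog = build_species_catalog()
    if species_name not in catalog:
        raise ValueError(f"unknown species {species_name!r}")
    sp = catalog[species_name]
    depths: dict[tuple[str, str], float] = {}
    for ca in set(sp.patch_classes):
        for cb in set(sp.patch_classes):
            if species_name == "4v-selective" and ca.label != cb.label:
                d = 0.0
            else:
                d = _combined_depth(ca, cb)
            depths[tuple(sorted((ca.label, cb.label)))] = d  # type: ignore[index]
    return MixtureSpec(
        name=f"pure-{species_name}",
        composition=((sp, count),),
        matrix=InteractionMatrix(depths),
    )


def effective_valency(species: SpeciesSpec, matrix: InteractionMatrix) -> float:
    """Per-patch best realizable depth, summed over patches, in epsilon units.

    For each patch this is the largest well depth it can reach against any
    partner class known to the matrix; a species whose sites are globally
    inert has zero effective valency in that mixture.
    """
    partners = matrix.labels()
    total = 0.0
    for c in species.patch_classes:
        best = 0.0
        for p in partners:
            if (c.label, p) in matrix:
                best = max(best, matrix.depth(c.label, p))
        total += best
    return total


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

def mixture_to_dict(mix: MixtureSpec) -> dict:
    return {
        "name": mix.name,
        "species": [
            {
                "name": sp.name,
                "count": count,
                "patches": [
                    {
                        "direction": [float(x) for x in d],
                        "class": c.label,
                        "strength": c.intrinsic_strength,
                    }
                    for d, c in zip(sp.patch_directions, sp.patch_classes)
                ],
            }
            for sp, count in mix.composition
        ],
        "matrix": [
            {"pair": [a, b], "depth": d} for (a, b), d in sorted(mix.matrix.entries.items())
        ],
    }


def mixture_from_dict(data: Mapping) -> MixtureSpec:
    classes: dict[str, PatchClass] = {}
    composition = []
    for sp in data["species"]:
        patch_dirs = []
        patch_classes = []
        for p in sp["patches"]:
            label = p["class"]
            strength = float(p.get("strength", 1.0))
            if label not in classes:
                classes[label] = PatchClass(label, strength)
            elif classes[label].intrinsic_strength != strength:
                raise ValueError(f"patch class {label!r} redefined with a different strength")
            patch_dirs.append(tuple(float(x) for x in p["direction"]))
            patch_classes.append(classes[label])
        composition.append(
            (SpeciesSpec(sp["name"], tuple(patch_dirs), tuple(patch_classes)), int(sp["count"]))
        )
    depths = {tuple(e["pair"]): float(e["depth"]) for e in data["matrix"]}
    return MixtureSpec(
        name=data.get("name", "custom"),
        composition=tuple(composition),
        matrix=InteractionMatrix(depths),  # type: ignore[arg-type]
    )


def save_mixture(mix: MixtureSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(mixture_to_dict(mix), fh, sort_keys=False)


def load_mixture(path) -> MixtureSpec:
    with open(path) as fh:
        return mixture_from_dict(yaml.safe_load(fh))
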