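"""Seeded generators of protein families and gene neighborhoods with ground truth.

The family generator emulates the statistical structure the pipeline assumes:
a multidomain architecture whose "ordered" regions draw from a
hydrophobic-biased composition and whose "disordered" linkers draw from a
charge/disorder-biased composition, diverged along a species tree with
per-region substitution probabilities and (by default linker-only) indels.
The neighborhood generator plants an exact shared-gene fraction between a
reference window and a counterpart window. All outputs are deterministic in
the seed; planted parameters are returned as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import dendropy
import numpy as np
import yaml

from .errors import ParameterError, SimulationError, ValidationError
from .genomic_neighborhood import Gene, GeneNeighborhood
from .records import AA20, DomainAnnotation, ProteinRecord

ORDERED = "ordered"
DISORDERED = "disordered"


class Region(NamedTuple):
    name: str
    length: int
    region_class: str  # ORDERED or DISORDERED


def default_compositions() -> dict[str, dict[str, float]]:
    """The shipped ordered/disordered amino-acid composition vectors."""
    with resources.files("disevo.data").joinpath("compositions.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered list of regions plus per-class residue compositions."""

    regions: tuple[Region, ...]
    compositions: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_compositions
    )

    def __post_init__(self) -> None:
        if not self.regions:
            raise ParameterError("architecture needs at least one region")
        for r in self.regions:
            if r.length < 1:
                raise ValidationError(f"region {r.name!r}: length must be >= 1")
            if r.region_class not in self.compositions:
                raise ValidationError(
                    f"region {r.name!r}: no composition for class {r.region_class!r}"
                )
        for cls, comp in self.compositions.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(f"composition {cls!r} sums to {total}, not 1")
            for aa in comp:
                if aa not in AA20:
                    raise ValidationError(f"composition {cls!r}: unknown residue {aa!r}")

    def total_length(self) -> int:
        return sum(r.length for r in self.regions)


def dbc1_like_architecture() -> ArchitectureSpec:
    """A compact multidomain layout emulating a DBC1/CCAR1-style protein.

    Ordered domains (S1-Like, LZ, Nudix, EF-Hand) separated by disordered
    linkers and flanked by a disordered N-terminus/NLS and C-terminal tail.
    Lengths are desk-scale, not copies of the real proteins.
    """
    return ArchitectureSpec(
        regions=(
            Region("Nterm", 40, DISORDERED),
            Region("S1-Like", 70, ORDERED),
            Region("NLS", 25, DISORDERED),
            Region("LZ", 30, ORDERED),
            Region("linker1", 50, DISORDERED),
            Region("Nudix", 80, ORDERED),
            Region("linker2", 45, DISORDERED),
            Region("EF-Hand", 40, ORDERED),
            Region("CC2", 50, DISORDERED),
        )
    )


@dataclass(frozen=True)
class EvolutionSpec:
    """Species tree plus per-region divergence parameters.

    ``tree_newick`` carries branch lengths; ``groups`` maps each leaf label to
    its species-group label. ``region_rates`` gives the per-site substitution
    probability per unit branch length for each region name (falling back to
    ``class_rates`` by region class). Indels occur at ``indel_rate`` expected
    events per site per unit branch length, with geometric lengths
    (parameter ``indel_length_p``), confined to disordered regions unless
    ``indels_anywhere``.
    """

    tree_newick: str
    groups: Mapping[str, str]
    region_rates: Mapping[str, float] = field(default_factory=dict)
    class_rates: Mapping[str, float] = field(
        default_factory=lambda: {ORDERED: 0.05, DISORDERED: 0.4}
    )
    indel_rate: float = 0.0
    indel_length_p: float = 0.5
    indels_anywhere: bool = False
    seed: int = 0

    def rate_for(self, region: Region) -> float:
        if region.name in self.region_rates:
            return float(self.region_rates[region.name])
        return float(self.class_rates[region.region_class])


def sample_ancestor(
    arch: ArchitectureSpec, seed: int, record_id: str = "ancestor"
) -> tuple[ProteinRecord, list[DomainAnnotation]]:
    """Draw an ancestral sequence i.i.d. from the per-region compositions.

    Annotations cover every region (domains and linkers alike) at the exact
    planted boundaries, 1-based inclusive on the ancestor.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    annotations: list[DomainAnnotation] = []
    pos = 0
    for region in arch.regions:
        comp = arch.compositions[region.region_class]
        letters = sorted(comp)
        probs = np.array([comp[a] for a in letters])
        probs = probs / probs.sum()
        seq = "".join(rng.choice(letters, size=region.length, p=probs))
        parts.append(seq)
        annotations.append(
            DomainAnnotation(
                reference_id=record_id,
                domain_name=region.name,
                start=pos + 1,
                end=pos + region.length,
            )
        )
        pos += region.length
    record = ProteinRecord(id=record_id, sequence="".join(parts), species="ancestor")
    return record, annotations


def _mutate_region(
    seq: str,
    region: Region,
    comp: Mapping[str, float],
    p_sub: float,
    indel_rate: float,
    indel_length_p: float,
    allow_indels: bool,
    rng: np.random.Generator,
) -> str:
    letters = sorted(comp)
    probs = np.array([comp[a] for a in letters])
    probs = probs / probs.sum()
    chars = list(seq)
    if p_sub > 0:
        hits = np.nonzero(rng.random(len(chars)) < min(p_sub, 1.0))[0]
        for i in hits:
            # replacement differs from the current residue, so the planted
            # probability is the expected per-site mismatch from the parent
            while True:
                new = rng.choice(letters, p=probs)
                if new != chars[i]:
                    chars[i] = new
                    break
    if allow_indels and indel_rate > 0:
        n_events = rng.poisson(indel_rate * len(chars))
        for _ in range(n_events):
            length = int(rng.geometric(indel_length_p))
            if rng.random() < 0.5 and len(chars) > length:
                pos = int(rng.integers(0, len(chars) - length + 1))
                del chars[pos : pos + length]
            else:
                pos = int(rng.integers(0, len(chars) + 1))
                insert = rng.choice(letters, size=length, p=probs)
                chars[pos:pos] = list(insert)
    if not chars:
        raise SimulationError(
            f"region {region.name!r} was eliminated by deletions; rerun with a new seed"
        )
    return "".join(chars)


def evolve_family(
    ancestor_regions: Sequence[str] | tuple[ProteinRecord, Sequence[DomainAnnotation]],
    arch: ArchitectureSpec,
    spec: EvolutionSpec,
) -> tuple[list[ProteinRecord], dict]:
    """Evolve an ancestor along the species tree; return leaves + ground truth.

    ``ancestor_regions`` is either the (record, annotations) pair from
    :func:`sample_ancestor` or a pre-split list of per-region strings.
    Substitutions are applied per region with probability ``rate * branch
    length`` per site (capped at 1); indels likewise scaled by branch length.
    Regions evolve independently, so leaf domain boundaries stay known. The
    truth dict records planted rates and realized mean leaf-vs-ancestor
    divergence per region.
    """
    if isinstance(ancestor_regions[0], ProteinRecord):
        record, annotations = ancestor_regions  # type: ignore[misc]
        regions_seq = [
            record.sequence[a.interval[0] : a.interval[1]] for a in annotations
        ]
    else:
        regions_seq = list(ancestor_regions)  # type: ignore[arg-type]
    if len(regions_seq) != len(arch.regions):
        raise ParameterError("ancestor regions do not match the architecture")

    tree = dendropy.Tree.get(data=spec.tree_newick, schema="newick")
    rng = np.random.default_rng(spec.seed)
    leaves: list[ProteinRecord] = []
    leaf_regions: dict[str, list[str]] = {}

    def descend(node, state: list[str]) -> None:
        blen = node.edge.length or 0.0
        if blen > 0:
            state = [
                _mutate_region(
                    s,
                    region,
                    arch.compositions[region.region_class],
                    spec.rate_for(region) * blen,
                    spec.indel_rate * blen,
                    spec.indel_length_p,
                    spec.indels_anywhere or region.region_class == DISORDERED,
                    rng,
                )
                for s, region in zip(state, arch.regions)
            ]
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            label = label.replace(" ", "_")
            group = spec.groups.get(label, "")
            leaves.append(
                ProteinRecord(
                    id=label, sequence="".join(state), species=label, group=group
                )
            )
            leaf_regions[label] = list(state)
        else:
            for child in node.child_nodes():
                descend(child, list(state))

    descend(tree.seed_node, list(regions_seq))

    divergence: dict[str, float] = {}
    for k, region in enumerate(arch.regions):
        anc = regions_seq[k]
        per_leaf = []
        for label, regs in leaf_regions.items():
            leaf_seq = regs[k]
            if len(leaf_seq) == len(anc):
                per_leaf.append(
                    sum(a != b for a, b in zip(anc, leaf_seq)) / len(anc)
                )
        divergence[region.name] = float(np.mean(per_leaf)) if per_leaf else float("nan")

    truth = {
        "seed": spec.seed,
        "planted_rates": {r.name: spec.rate_for(r) for r in arch.regions},
        "region_classes": {r.name: r.region_class for r in arch.regions},
        "realized_mean_divergence": divergence,
        "indel_rate": spec.indel_rate,
    }
    return leaves, truth


def two_group_star_spec(
    n_per_group: int = 20,
    diverged_length: float = 1.0,
    group_names: tuple[str, str] = ("reference", "diverged"),
    linker_rate: float = 0.4,
    domain_rate: float = 0.05,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> EvolutionSpec:
    """Benchmark design for planted-rate recovery: a two-group star tree.

    Group 1 leaves sit at divergence 0 from the ancestor (the reference
    group); group 2 leaves each diverge independently along a unit-length
    branch. The expected cross-group per-site mismatch probability of a
    region then equals its planted substitution rate exactly.
    """
    g1 = [f"ref_{i:02d}:0" for i in range(1, n_per_group + 1)]
    g2 = [f"div_{i:02d}:{diverged_length:g}" for i in range(1, n_per_group + 1)]
    newick = "(" + ",".join(g1 + g2) + ");"
    groups = {f"ref_{i:02d}": group_names[0] for i in range(1, n_per_group + 1)}
    groups.update({f"div_{i:02d}": group_names[1] for i in range(1, n_per_group + 1)})
    return EvolutionSpec(
        tree_newick=newick,
        groups=groups,
        class_rates={ORDERED: domain_rate, DISORDERED: linker_rate},
        indel_rate=indel_rate,
        seed=seed,
    )


def rate_benchmark_architecture(
    domain_length: int = 150, linker_length: int = 150
) -> ArchitectureSpec:
    """Two-region architecture (one ordered domain, one disordered linker)."""
    return ArchitectureSpec(
        regions=(
            Region("domain", domain_length, ORDERED),
            Region("linker", linker_length, DISORDERED),
        )
    )


def sample_class_sequences(
    region_class: str,
    n: int,
    length: int,
    seed: int,
    compositions: Mapping[str, Mapping[str, float]] | None = None,
    prefix: str | None = None,
) -> list[ProteinRecord]:
    """n i.i.d. single-class sequences (calibration/validation material)."""
    comps = compositions if compositions is not None else default_compositions()
    comp = comps[region_class]
    letters = sorted(comp)
    probs = np.array([comp[a] for a in letters])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    prefix = prefix if prefix is not None else region_class
    return [
        ProteinRecord(
            id=f"{prefix}_{i:03d}",
            sequence="".join(rng.choice(letters, size=length, p=probs)),
            species=f"synthetic_{i:03d}",
        )
        for i in range(n)
    ]


def make_neighborhoods(
    n_genes: int,
    shared_fraction: float,
    window_bp: int = 2_000_000,
    seed: int = 0,
    center_symbol: str = "CENTER",
    species: tuple[str, str] = ("human", "other"),
) -> tuple[GeneNeighborhood, GeneNeighborhood, dict]:
    """Paired neighborhoods with an exactly planted shared-gene fraction.

    The reference window holds ``n_genes`` genes around a center gene; the
    counterpart shares exactly ``round(shared_fraction * n_genes)`` symbols,
    the remainder replaced by novel symbols. Positions are jittered uniformly
    within the window. The center gene appears on both sides.
    """
    if not 0 <= shared_fraction <= 1:
        raise ParameterError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * n_genes))
    center_mid = 10_000_000
    half = window_bp // 2

    def place(symbols: Sequence[str], sp: str) -> GeneNeighborhood:
        gene_len = 1_000
        mids = rng.integers(
            center_mid - half + gene_len, center_mid + half - gene_len, size=len(symbols)
        )
        genes = [Gene(center_symbol, center_mid - gene_len // 2, center_mid + gene_len // 2)]
        for sym, mid in zip(symbols, mids):
            genes.append(Gene(sym, int(mid) - gene_len // 2, int(mid) + gene_len // 2))
        genes.sort(key=lambda g: g.start_bp)
        return GeneNeighborhood(species=sp, chromosome="1", genes=genes)

    shared = [f"SHARED{i:03d}" for i in range(n_shared)]
    human_only = [f"REFONLY{i:03d}" for i in range(n_genes - n_shared)]
    novel = [f"NOVEL{i:03d}" for i in range(n_genes - n_shared)]
    human_nb = place(shared + human_only, species[0])
    other_nb = place(shared + novel, species[1])
    truth = {
        "n_genes": n_genes,
        "shared_fraction": shared_fraction,
        "planted_shared": n_shared,
        "seed": seed,
        "center_symbol": center_symbol,
    }
    return human_nb, other_nb, truth
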