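"""Synthetic genome pairs, coverage, depth matrices and panels with ground truth.

The generator emulates the data a PAV study works from, at desk scale:

* a *donor* genome carrying segments that a second, *acceptor*, genome
  lacks.  Each planted deletion breakpoint carries an exact
  microhomology whose length is drawn from a geometric decay plus a
  spike at 5 bp (the LTR-retrotransposon target-site-duplication
  signature); the planted length is enforced exactly so truth and
  extraction can be compared base by base;
* decoy candidates that individual filter stages must reject:
  self-mapping artifacts, sub-threshold (< 1 kb) deletions, duplication
  decoys whose sequence is still present in the acceptor, poorly
  assembled regions, and oversize calls;
* per-base coverage profiles in which truly absent regions receive
  near-zero opposite-genotype depth (a configurable leak fraction of
  the base depth) and shared regions Poisson depth around the base;
* a regions x lines read-count matrix drawn from the two-component
  regression mixture on the square-root scale, with the cluster
  membership of every cell recorded;
* group-structured presence/absence frequencies, with optional
  group-private PAVs.

One global seed drives everything; independent sub-streams are derived
from stable stage labels, so adding a stage never shifts the draws of
another.  Identical configurations therefore produce byte-identical
outputs.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .discovery import CandidateSV, CoverageProfile
from .genotyper import DepthMatrix

__all__ = [
    "MicrohomologyMixture",
    "DepthModel",
    "GroupSpec",
    "SimulationConfig",
    "PlantedFeature",
    "TruthSet",
    "adversarial_config",
    "simulate_genome_pair",
    "simulate_coverage",
    "simulate_depth_matrix",
    "simulate_panel",
    "sample_mh_lengths",
    "candidates_from_truth",
    "simulate_ld_genotypes",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUE_PAV_CATEGORIES = ("anchored_unique", "anchored_ambiguous", "incomplete")
DECOY_CATEGORIES = ("subthreshold_decoy", "duplication_decoy", "selfmap_decoy",
                    "assembly_decoy", "oversize_decoy")


def _rng(seed: int, label: str) -> np.random.Generator:
    """Sub-stream derived from (seed, stage label); stable across stages."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class MicrohomologyMixture:
    """Breakpoint microhomology length law.

    With probability ``no_mh_prob`` a breakpoint carries no
    microhomology (length 0).  Otherwise the length follows a geometric
    decay with parameter ``geometric_p`` truncated to
    [``min_mh``, ``max_mh``] and renormalized to mass ``1 - spike_mass``,
    plus a point mass ``spike_mass`` at ``spike_at``.
    """

    geometric_p: float = 0.30
    spike_at: int = 5
    spike_mass: float = 0.10
    no_mh_prob: float = 0.60
    min_mh: int = 3
    max_mh: int = 37

    def __post_init__(self) -> None:
        if not (0 < self.geometric_p < 1):
            raise ValueError("geometric_p must lie in (0, 1)")
        if not (0 <= self.spike_mass < 1):
            raise ValueError("spike_mass must lie in [0, 1)")
        if not (0 <= self.no_mh_prob < 1):
            raise ValueError("no_mh_prob must lie in [0, 1)")
        if not (0 < self.min_mh <= self.spike_at <= self.max_mh):
            raise ValueError("need min_mh <= spike_at <= max_mh")

    def pmf(self) -> pd.Series:
        """Length -> probability over support {0} ∪ [min_mh, max_mh]."""
        ks = np.arange(self.min_mh, self.max_mh + 1)
        geo = self.geometric_p * (1 - self.geometric_p) ** (ks - self.min_mh)
        geo = geo / geo.sum() * (1 - self.spike_mass)
        cond = pd.Series(geo, index=ks)
        cond[self.spike_at] += self.spike_mass
        full = cond * (1 - self.no_mh_prob)
        full[0] = self.no_mh_prob
        return full.sort_index()


def sample_mh_lengths(mix: MicrohomologyMixture, n: int, rng: np.random.Generator) -> np.ndarray:
    pmf = mix.pmf()
    return rng.choice(pmf.index.to_numpy(), size=n, p=pmf.to_numpy())


@dataclass(frozen=True)
class DepthModel:
    """Sqrt-scale regression mixture parameters for panel read counts.

    Cluster 0 (absent) defaults to a flat background of sqrt-count 2
    (a few cross-mapping reads); cluster 1 (present) tracks the donor
    count one-to-one.
    """

    a0: float = 2.0
    b0: float = 0.0
    sigma0: float = 0.8
    a1: float = 0.0
    b1: float = 1.0
    sigma1: float = 0.8
    mixing: float = 0.5  # prior P(present) when no genotype panel constrains Z

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.sigma1 < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 < self.mixing < 1):
            raise ValueError("mixing proportion must lie in (0, 1)")


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_lines: int
    beta_params: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError(f"group {self.name!r} must contain at least one line")


def _default_groups() -> tuple[GroupSpec, ...]:
    # 23 panel lines across four temperate groups; the donor belongs to
    # the first group and the opposite reference to the last.
    return (
        GroupSpec("EuropeanFlint", 7, (2.5, 2.5)),
        GroupSpec("NorthernFlint", 5, (2.0, 3.0)),
        GroupSpec("CornBeltDent", 7, (1.0, 3.0)),
        GroupSpec("StiffStalk", 4, (0.8, 3.5)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 400_000
    n_pavs: int = 20
    pav_length_range: tuple[int, int] = (1000, 4000)
    n_ambiguous: int = 3          # of n_pavs, planted with a duplicated junction
    n_incomplete: int = 5         # donor-only scaffolds, no shared flanks
    incomplete_length_range: tuple[int, int] = (3000, 10_000)
    n_subthreshold_decoys: int = 0
    subthreshold_length_range: tuple[int, int] = (300, 999)
    n_duplication_decoys: int = 0
    n_selfmap_decoys: int = 0
    n_assembly_decoys: int = 0
    n_oversize_decoys: int = 0
    oversize_decoy_length: int = 250_000
    flank: int = 100              # anchoring flank; also junction-copy arm length
    mh: MicrohomologyMixture = field(default_factory=MicrohomologyMixture)
    depth: DepthModel = field(default_factory=DepthModel)
    base_depth: float = 40.0
    leak_fraction: float = 0.001  # opposite-genotype depth over absent regions
    x_sqrt_range: tuple[float, float] = (10.0, 40.0)
    noise_model: str = "gaussian_sqrt"  # or "poisson" (model-misspecified mode)
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    n_group_private: int = 2
    donor_line: str = "F2"
    reference_line: str = "B73"

    def __post_init__(self) -> None:
        if self.n_pavs < 0 or self.n_ambiguous > max(self.n_pavs, 0):
            raise ValueError("need 0 <= n_ambiguous <= n_pavs")
        for lo, hi in (self.pav_length_range, self.incomplete_length_range,
                       self.subthreshold_length_range):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must satisfy 0 < lo <= hi")
        if self.noise_model not in ("gaussian_sqrt", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not self.groups:
            raise ValueError("group specification must be nonempty")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "mh" in d and isinstance(d["mh"], Mapping):
            d["mh"] = MicrohomologyMixture(**d["mh"])
        if "depth" in d and isinstance(d["depth"], Mapping):
            d["depth"] = DepthModel(**d["depth"])
        if "groups" in d:
            d["groups"] = tuple(
                g if isinstance(g, GroupSpec) else GroupSpec(*g) if isinstance(g, (list, tuple))
                else GroupSpec(**g)
                for g in d["groups"])
        for key in ("pav_length_range", "incomplete_length_range",
                    "subthreshold_length_range", "x_sqrt_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def adversarial_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration planting at least one decoy for every filter stage."""
    defaults = dict(
        seed=seed, genome_length=1_500_000, n_pavs=20, n_ambiguous=3,
        n_incomplete=5, n_subthreshold_decoys=3, n_duplication_decoys=3,
        n_selfmap_decoys=2, n_assembly_decoys=2, n_oversize_decoys=1,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class PlantedFeature:
    """One planted interval with its ground truth."""

    id: str
    contig: str
    start: int
    end: int
    category: str
    removed: bool
    mh_length: int | None = None
    detected_in_self_mapping: bool = False
    anchor_copies: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Everything the generator knows: planted features, genotypes, clusters."""

    features: list[PlantedFeature]
    donor_lengths: dict[str, int]
    acceptor_length: int
    config: SimulationConfig
    genotypes: pd.DataFrame | None = None      # PAV x line in {0, 1}
    groups: dict[str, str] | None = None       # line -> group
    group_freqs: pd.DataFrame | None = None    # PAV x group drawn frequencies

    @property
    def true_pavs(self) -> list[PlantedFeature]:
        return [f for f in self.features if f.category in TRUE_PAV_CATEGORIES]

    @property
    def decoys(self) -> list[PlantedFeature]:
        return [f for f in self.features if f.category in DECOY_CATEGORIES]

    @property
    def removed_length(self) -> int:
        return sum(f.length for f in self.features if f.removed)

    def mh_lengths(self) -> dict[str, int]:
        return {f.id: f.mh_length for f in self.features
                if f.category in ("anchored_unique", "anchored_ambiguous")}

    def acceptor_breakpoint(self, pav_id: str) -> int:
        """Expected acceptor-coordinate junction of a removed chr1 feature."""
        target = next(f for f in self.features if f.id == pav_id)
        if not target.removed:
            raise ValueError(f"{pav_id} was not removed from the acceptor")
        shift = sum(f.length for f in self.features
                    if f.removed and f.contig == target.contig and f.start < target.start)
        return target.start - shift


def _draw_lengths(rng, n, lo_hi):
    lo, hi = lo_hi
    return rng.integers(lo, hi + 1, size=n)


def simulate_genome_pair(config: SimulationConfig):
    """Build (donor sequences, acceptor sequences, truth).

    The donor is one random chromosome ``chr1`` plus ``n_incomplete``
    standalone scaffolds; the acceptor equals ``chr1`` with every
    removed feature excised.  Raises ValueError naming the constraint if
    the requested features cannot be packed into ``genome_length``.
    """
    rng = _rng(config.seed, "genome")
    mh_rng = _rng(config.seed, "microhomology")
    flank = config.flank

    # --- decide the feature roster -------------------------------------
    specs: list[tuple[str, str, int, bool, bool]] = []  # (id, category, length, removed, selfmap)
    n_unique = config.n_pavs - config.n_ambiguous
    for i in range(n_unique):
        specs.append((f"pav_{i + 1:04d}", "anchored_unique",
                      int(_draw_lengths(rng, 1, config.pav_length_range)[0]), True, False))
    for i in range(config.n_ambiguous):
        specs.append((f"pav_amb_{i + 1:04d}", "anchored_ambiguous",
                      int(_draw_lengths(rng, 1, config.pav_length_range)[0]), True, False))
    for i in range(config.n_subthreshold_decoys):
        specs.append((f"decoy_sub_{i + 1:02d}", "subthreshold_decoy",
                      int(_draw_lengths(rng, 1, config.subthreshold_length_range)[0]), True, False))
    for i in range(config.n_selfmap_decoys):
        specs.append((f"decoy_self_{i + 1:02d}", "selfmap_decoy",
                      int(_draw_lengths(rng, 1, config.pav_length_range)[0]), True, True))
    for i in range(config.n_assembly_decoys):
        specs.append((f"decoy_asm_{i + 1:02d}", "assembly_decoy",
                      int(_draw_lengths(rng, 1, config.pav_length_range)[0]), True, False))
    for i in range(config.n_oversize_decoys):
        specs.append((f"decoy_over_{i + 1:02d}", "oversize_decoy",
                      config.oversize_decoy_length, True, False))
    for i in range(config.n_duplication_decoys):
        specs.append((f"decoy_dup_{i + 1:02d}", "duplication_decoy",
                      int(_draw_lengths(rng, 1, config.pav_length_range)[0]), False, False))
    # slots reserved for the extra junction copies of ambiguous PAVs
    n_copy_slots = config.n_ambiguous

    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    # --- pack features onto chr1 ---------------------------------------
    min_gap = 2 * flank + 60
    cursor = min_gap
    placements: list[tuple[str, str, int, int, bool, bool]] = []
    for sid, cat, length, removed, selfmap in specs:
        start = cursor + int(rng.integers(0, 400))
        end = start + length
        cursor = end + min_gap
        placements.append((sid, cat, start, end, removed, selfmap))
    copy_slots = []
    for i in range(n_copy_slots):
        start = cursor + int(rng.integers(0, 400))
        copy_slots.append(start)
        cursor = start + 2 * flank + min_gap
    if cursor + min_gap > config.genome_length:
        raise ValueError(
            f"genome_length={config.genome_length} too small: packing the planted "
            f"features requires at least {cursor + min_gap} bp")

    donor_arr = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)

    # --- plant microhomology and record truth ---------------------------
    features: list[PlantedFeature] = []
    anchored = [p for p in placements if p[1] in ("anchored_unique", "anchored_ambiguous")]
    mh_lengths = sample_mh_lengths(config.mh, len(anchored), mh_rng)
    mh_iter = iter(mh_lengths)
    for sid, cat, start, end, removed, selfmap in placements:
        mh = None
        if cat in ("anchored_unique", "anchored_ambiguous"):
            mh = int(next(mh_iter))
            _plant_exact_mh(donor_arr, start, end, mh, rng)
        features.append(PlantedFeature(
            id=sid, contig="chr1", start=start, end=end, category=cat,
            removed=removed, mh_length=mh, detected_in_self_mapping=selfmap,
            anchor_copies=2 if cat == "anchored_ambiguous" else 1))

    # duplicate the junction of each ambiguous PAV elsewhere on chr1
    amb = [f for f in features if f.category == "anchored_ambiguous"]
    for feat, slot in zip(amb, copy_slots):
        left = donor_arr[feat.start - flank : feat.start]
        right = donor_arr[feat.end : feat.end + flank]
        donor_arr[slot : slot + flank] = left
        donor_arr[slot + flank : slot + 2 * flank] = right

    donor_chr1 = _BASES[donor_arr].tobytes().decode("ascii")

    # --- excise removed features to obtain the acceptor -----------------
    keep = np.ones(config.genome_length, dtype=bool)
    for f in features:
        if f.removed:
            keep[f.start : f.end] = False
    acceptor_chr1 = _BASES[donor_arr[keep]].tobytes().decode("ascii")

    donor: dict[str, str] = {"chr1": donor_chr1}
    scaf_rng = _rng(config.seed, "scaffolds")
    for i in range(config.n_incomplete):
        length = int(_draw_lengths(scaf_rng, 1, config.incomplete_length_range)[0])
        arr = scaf_rng.integers(0, 4, size=length, dtype=np.uint8)
        name = f"scaffold_{i + 1:04d}"
        donor[name] = _BASES[arr].tobytes().decode("ascii")
        features.append(PlantedFeature(
            id=name, contig=name, start=0, end=length,
            category="incomplete", removed=False, mh_length=None))

    truth = TruthSet(
        features=features,
        donor_lengths={k: len(v) for k, v in donor.items()},
        acceptor_length=len(acceptor_chr1),
        config=config,
    )
    return donor, {"chr1": acceptor_chr1}, truth


def _plant_exact_mh(arr: np.ndarray, start: int, end: int, k: int, rng) -> None:
    """Force the maximal microhomology at [start, end) to be exactly k, on the right.

    Copies the first k deleted bases over the k bases following the
    deletion, then breaks any chance extension: position end+k must
    mismatch start+k (right side stops at k) and the bases just before
    start/end must mismatch (left side contributes 0, which also pins
    the leftmost canonical placement of the deletion window).
    """
    if k > 0:
        arr[end : end + k] = arr[start : start + k]
    _force_mismatch(arr, start + k, end + k, rng)   # cap the right side
    _force_mismatch(arr, start - 1, end - 1, rng)   # zero the left side


def _force_mismatch(arr: np.ndarray, i: int, j: int, rng) -> None:
    if arr[i] == arr[j]:
        arr[j] = (arr[j] + 1 + rng.integers(0, 3)) % 4


def simulate_coverage(truth: TruthSet, config: SimulationConfig | None = None):
    """Per-contig coverage profiles: (opposite-genotype, own-genotype).

    Opposite depth is Poisson around ``base_depth`` over shared
    sequence, around ``leak_fraction * base_depth`` over removed
    features and incomplete scaffolds, and stays at base depth over
    duplication decoys (their sequence is present elsewhere in the
    acceptor).  Own-genotype properly-paired depth is Poisson around
    ``base_depth`` except over assembly decoys, where it is zero.
    """
    config = config or truth.config
    if config.base_depth < 0:
        raise ValueError("base_depth must be >= 0")
    rng = _rng(config.seed, "coverage")
    leak = config.leak_fraction * config.base_depth

    opposite: dict[str, CoverageProfile] = {}
    own: dict[str, CoverageProfile] = {}
    for contig, length in truth.donor_lengths.items():
        lam_opp = np.full(length, float(config.base_depth))
        lam_proper = np.full(length, float(config.base_depth))
        for f in truth.features:
            if f.contig != contig:
                continue
            if f.removed or f.category == "incomplete":
                lam_opp[f.start : f.end] = leak
            if f.category == "assembly_decoy":
                lam_proper[f.start : f.end] = 0.0
        depth_opp = rng.poisson(lam_opp)
        depth_own = rng.poisson(np.full(length, float(config.base_depth)))
        proper_own = rng.poisson(lam_proper)
        opposite[contig] = CoverageProfile(contig, 0, length, depth_opp)
        own[contig] = CoverageProfile(contig, 0, length, depth_own, proper_own)
    return opposite, own


def simulate_panel(truth: TruthSet, config: SimulationConfig | None = None):
    """Draw group-structured presence/absence genotypes for the panel.

    Per PAV and group, a presence frequency is drawn from that group's
    Beta law; lines then carry the PAV independently with that
    frequency.  The first ``n_group_private`` PAVs are made private to
    the donor's group (zero frequency elsewhere, at least one group
    carrier).  The donor line carries every PAV; the opposite reference
    carries none.  Results are stored on the truth set and returned as
    (genotype matrix, line -> group map).
    """
    config = config or truth.config
    rng = _rng(config.seed, "panel")
    pav_ids = [f.id for f in truth.true_pavs]
    if not pav_ids:
        genotypes = pd.DataFrame(index=[], columns=[config.donor_line, config.reference_line])
        truth.genotypes = genotypes
        truth.groups = {config.donor_line: config.groups[0].name,
                        config.reference_line: config.groups[-1].name}
        return genotypes, truth.groups

    groups: dict[str, str] = {}
    donor_group = config.groups[0].name
    reference_group = config.groups[-1].name
    line_names: list[str] = [config.donor_line, config.reference_line]
    groups[config.donor_line] = donor_group
    groups[config.reference_line] = reference_group
    for g in config.groups:
        for i in range(g.n_lines):
            name = f"{g.name}_{i + 1:02d}"
            line_names.append(name)
            groups[name] = g.name

    freqs = pd.DataFrame(index=pav_ids, columns=[g.name for g in config.groups], dtype=float)
    for g in config.groups:
        a, b = g.beta_params
        freqs[g.name] = rng.beta(a, b, size=len(pav_ids))
    private = pav_ids[: config.n_group_private]
    for pav in private:
        for g in config.groups:
            if g.name != donor_group:
                freqs.loc[pav, g.name] = 0.0

    genotypes = pd.DataFrame(0, index=pav_ids, columns=line_names, dtype=int)
    genotypes[config.donor_line] = 1
    genotypes[config.reference_line] = 0
    for g in config.groups:
        members = [l for l in line_names if groups[l] == g.name
                   and l not in (config.donor_line, config.reference_line)]
        if not members:
            continue
        draws = rng.random((len(pav_ids), len(members))) < freqs[g.name].to_numpy()[:, None]
        genotypes.loc[:, members] = draws.astype(int)
    for pav in private:
        members = [l for l in line_names if groups[l] == donor_group
                   and l not in (config.donor_line, config.reference_line)]
        if members and genotypes.loc[pav, members].sum() == 0:
            genotypes.loc[pav, members[0]] = 1

    truth.genotypes = genotypes
    truth.groups = groups
    truth.group_freqs = freqs
    return genotypes, groups


def simulate_depth_matrix(truth: TruthSet, config: SimulationConfig | None = None) -> DepthMatrix:
    """Panel read counts from the sqrt-scale regression mixture.

    The donor copy number x_i is drawn uniformly on ``x_sqrt_range``
    (sqrt scale); the donor column stores x_i^2.  Every other line's
    sqrt count is a_Z + b_Z x_i + sigma_Z * N(0,1) given its true
    cluster membership Z from the genotype panel, truncated at zero and
    squared back to a raw count.  In ``poisson`` mode counts are instead
    Poisson with mean (a_Z + b_Z x_i)^2, deliberately violating the
    Gaussian-on-sqrt assumption for robustness checks.
    """
    config = config or truth.config
    dp = config.depth
    if dp.sigma0 < 0 or dp.sigma1 < 0:
        raise ValueError("sigma must be >= 0")
    if truth.genotypes is None:
        simulate_panel(truth, config)
    genotypes = truth.genotypes
    pav_ids = list(genotypes.index)
    if not pav_ids:
        raise ValueError("no true PAVs to genotype")
    rng = _rng(config.seed, "depth_matrix")
    x = rng.uniform(*config.x_sqrt_range, size=len(pav_ids))

    counts = pd.DataFrame(index=pav_ids, dtype=float)
    counts[config.donor_line] = x**2
    for line in genotypes.columns:
        if line == config.donor_line:
            continue
        z = genotypes[line].to_numpy()
        a = np.where(z == 1, dp.a1, dp.a0)
        b = np.where(z == 1, dp.b1, dp.b0)
        sigma = np.where(z == 1, dp.sigma1, dp.sigma0)
        mean_sqrt = a + b * x
        if config.noise_model == "gaussian_sqrt":
            y = mean_sqrt + sigma * rng.standard_normal(len(pav_ids))
            counts[line] = np.maximum(y, 0.0) ** 2
        else:
            counts[line] = rng.poisson(np.maximum(mean_sqrt, 0.0) ** 2).astype(float)
    return DepthMatrix(counts, donor=config.donor_line)


def simulate_mixture_xy(
    depth: DepthModel,
    n: int,
    x_range: tuple[float, float] = (10.0, 40.0),
    seed: int = 0,
):
    """Draw (x, y, z) directly from the sqrt-scale regression mixture.

    Unlike :func:`simulate_depth_matrix`, no count constraint is
    imposed: y may be negative, so the Gaussian model holds exactly.
    Used for calibration and recovery studies of the genotyper itself.
    """
    rng = _rng(seed, "mixture")
    x = rng.uniform(*x_range, size=n)
    z = rng.random(n) < depth.mixing
    a = np.where(z, depth.a1, depth.a0)
    b = np.where(z, depth.b1, depth.b0)
    sigma = np.where(z, depth.sigma1, depth.sigma0)
    y = a + b * x + sigma * rng.standard_normal(n)
    return x, y, z.astype(int)


def candidates_from_truth(truth: TruthSet, caller_support: int = 10) -> list[CandidateSV]:
    """Candidate SV table as an external caller would report it."""
    out = []
    for f in truth.features:
        if f.category == "incomplete":
            continue  # scaffolds never reach SV calling
        out.append(CandidateSV(
            id=f.id, contig=f.contig, start=f.start, end=f.end,
            caller_support=caller_support,
            detected_in_self_mapping=f.detected_in_self_mapping))
    return out


def simulate_ld_genotypes(
    positions: np.ndarray,
    n_lines: int,
    decay_length: float,
    freq: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Biallelic genotypes (loci x lines) with distance-decaying LD.

    A latent Gaussian per line with covariance exp(-|d|/decay_length)
    between loci is thresholded at the ``freq`` quantile, so allele
    correlation falls monotonically with distance; ``decay_length=inf``
    yields fully linked loci (r2 = 1 between all pairs).
    """
    positions = np.asarray(positions, dtype=float)
    rng = _rng(seed, "ld")
    if np.isinf(decay_length):
        cov = np.ones((len(positions), len(positions)))
    else:
        d = np.abs(positions[:, None] - positions[None, :])
        cov = np.exp(-d / decay_length)
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(len(positions)))
    z = chol @ rng.standard_normal((len(positions), n_lines))
    from scipy.stats import norm as _norm

    return (z < _norm.ppf(freq)).astype(float)
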