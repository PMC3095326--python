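"""Synthetic clone-library generator with full ground truth.

Emulates a hierarchical clone-library survey of root-associated fungal ITS
diversity: a metacommunity of reference OTUs with conserved 5.8S and
divergent ITS1/ITS2 regions is distributed over a nested sampling design
(main localities > sub-localities > root systems), and a fixed number of
cloned ITS fragments is drawn per root system, subject to PCR point errors
and PCR-mediated chimera formation.  Every emitted clone carries ground-truth
labels (source OTU, chimera parents and breakpoint, error positions) so that
downstream QC and clustering can be scored against the truth.

The generator is deliberately simple where realism does not matter for the
statistics under test: sequences evolve by substitutions only (no indels, no
secondary structure), the 5.8S region is perfectly conserved, and community
structure is controlled by explicit OTU pools at each level of the hierarchy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .qc import CloneRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_POOL_LEVELS = ("private", "sub", "main", "global")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey.

    The defaults reproduce the design of the emulated study: 4 main
    localities, 3 sub-localities each, 2 root systems per sub-locality and
    24 sequenced clones per root system (576 authentic clones), with 137
    true OTUs and a 0.8% per-clone chimera rate.
    """

    n_main_localities: int = 4
    n_sublocalities_per_main: int = 3
    n_root_systems_per_sub: int = 2
    clones_per_root_system: int = 24
    n_true_otus: int = 137
    abundance_model: Literal["lognormal", "logseries"] = "lognormal"
    abundance_sdlog: float = 1.5
    logseries_alpha: float = 20.0
    # Share of each root system's community drawn from root-system-private /
    # sub-locality / main-locality pools; the remainder comes from a pool
    # shared by the whole metacommunity.
    turnover: tuple[float, float, float] = (0.75, 0.10, 0.10)
    chimera_rate: float = 0.008
    replace_chimeras: bool = True
    pcr_error_rate: float = 0.0002
    region_lengths: tuple[int, int, int] = (150, 160, 180)
    interspecies_divergence: float = 0.10
    min_interspecies_divergence: float = 0.065
    intraspecies_divergence: float = 0.01
    variant_count_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    chimera_breakpoint: Literal["junction", "uniform"] = "junction"
    otus_per_genus: int = 3
    genera_per_family: int = 4
    seed: int = 0

    @property
    def n_root_systems(self) -> int:
        return (
            self.n_main_localities
            * self.n_sublocalities_per_main
            * self.n_root_systems_per_sub
        )

    @property
    def total_length(self) -> int:
        return sum(self.region_lengths)

    def validate(self) -> None:
        for name in (
            "n_main_localities",
            "n_sublocalities_per_main",
            "n_root_systems_per_sub",
            "clones_per_root_system",
            "n_true_otus",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("chimera_rate", "pcr_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if len(self.turnover) != 3 or any(not 0 <= t <= 1 for t in self.turnover):
            raise ValueError("turnover must be three fractions in [0, 1]")
        if sum(self.turnover) > 1.0 + 1e-9:
            raise ValueError("turnover fractions must sum to at most 1")
        if any(l < 1 for l in self.region_lengths):
            raise ValueError("region_lengths must be positive")
        if not 0 <= self.intraspecies_divergence <= 1:
            raise ValueError("intraspecies_divergence must lie in [0, 1]")
        if not 0 < self.interspecies_divergence <= 1:
            raise ValueError("interspecies_divergence must lie in (0, 1]")
        if self.intraspecies_divergence >= self.interspecies_divergence:
            raise ValueError(
                "intraspecies_divergence must be smaller than "
                "interspecies_divergence for a well-posed recovery test"
            )
        if self.abundance_model not in ("lognormal", "logseries"):
            raise ValueError(f"unknown abundance_model {self.abundance_model!r}")
        if self.chimera_breakpoint not in ("junction", "uniform"):
            raise ValueError(f"unknown chimera_breakpoint {self.chimera_breakpoint!r}")

    def hierarchy(self) -> pd.DataFrame:
        """Root-system table with main-locality and sub-locality labels."""
        rows = []
        for i in range(1, self.n_main_localities + 1):
            for j in range(1, self.n_sublocalities_per_main + 1):
                for k in range(1, self.n_root_systems_per_sub + 1):
                    rows.append(
                        {
                            "main_locality": f"M{i}",
                            "sub_locality": f"M{i}S{j}",
                            "root_system": f"M{i}S{j}R{k}",
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class Metacommunity:
    """Reference OTUs, their genotype variants, abundances and pools."""

    config: SimulationConfig
    references: pd.DataFrame  # otu_id, sequence, species, genus, family, bounds
    variants: dict[str, list[str]]  # otu_id -> variant sequences (index 0 = ref)
    abundance: dict[str, float]
    pools: dict[str, dict[str, list[str]]]  # root_system -> level -> otu ids

    @property
    def otu_ids(self) -> list[str]:
        return list(self.references["otu_id"])

    def region_bounds(self) -> tuple[int, int]:
        l1, l2, _ = self.config.region_lengths
        return l1, l1 + l2

    @property
    def conserved_5p8s(self) -> str:
        its1_end, fivep8s_end = self.region_bounds()
        return self.references["sequence"].iloc[0][its1_end:fivep8s_end]


@dataclass
class SimulationTruth:
    """Ground-truth labels for every emitted clone."""

    clones: pd.DataFrame  # clone_id, otu, genotype, is_chimera, parents, ...
    community: Metacommunity

    def chimera_ids(self) -> set[str]:
        return set(self.clones.loc[self.clones["is_chimera"], "clone_id"])

    def incidence(self) -> pd.DataFrame:
        """True OTU x root-system incidence of the non-chimaeric clones."""
        df = self.clones[~self.clones["is_chimera"]]
        inc = pd.crosstab(df["otu"], df["root_system"]).clip(upper=1)
        return inc.astype(int)


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each listed position with a uniformly chosen different base."""
    out = seq.copy()
    for p in positions:
        choices = BASES[BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _partition_pools(
    otu_ids: list[str], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, dict[str, list[str]]]:
    """Allocate OTUs to private / sub-locality / main-locality / shared pools.

    The OTU list is partitioned (pools at the same level are disjoint), with
    the share of OTUs at each level proportional to the corresponding
    turnover fraction; the remainder forms one pool shared by all root
    systems.
    """
    f_priv, f_sub, f_main = config.turnover
    n = len(otu_ids)
    ids = list(rng.permutation(otu_ids))
    n_priv = round(f_priv * n)
    n_sub = round(f_sub * n)
    n_main = round(f_main * n)
    overshoot = n_priv + n_sub + n_main - n
    if overshoot > 0:
        n_main = max(0, n_main - overshoot)
    hier = config.hierarchy()
    private_split = np.array_split(ids[:n_priv], len(hier))
    sub_labels = hier["sub_locality"].unique()
    sub_split = np.array_split(ids[n_priv : n_priv + n_sub], len(sub_labels))
    main_labels = hier["main_locality"].unique()
    main_split = np.array_split(
        ids[n_priv + n_sub : n_priv + n_sub + n_main], len(main_labels)
    )
    global_pool = ids[n_priv + n_sub + n_main :]
    sub_pool = {s: list(p) for s, p in zip(sub_labels, sub_split)}
    main_pool = {m: list(p) for m, p in zip(main_labels, main_split)}
    pools: dict[str, dict[str, list[str]]] = {}
    for idx, row in hier.iterrows():
        pools[row["root_system"]] = {
            "private": list(private_split[idx]),
            "sub": sub_pool[row["sub_locality"]],
            "main": main_pool[row["main_locality"]],
            "global": list(global_pool),
        }
    return pools


def generate_metacommunity(config: SimulationConfig) -> Metacommunity:
    """Build the reference community: OTU sequences, taxonomy, pools.

    OTU references descend from a single random ancestor along a star
    phylogeny; ITS1/ITS2 sites mutate independently in each OTU while the
    5.8S region is untouched, so all references share an identical conserved
    core.  References are resampled until every pair differs at a fraction
    of ITS sites of at least ``min_interspecies_divergence``, which keeps
    distinct OTUs separable at the clustering threshold even after
    within-OTU variants shift sequences by a few bases.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_refs, rng_pools, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    l1, l2, l3 = config.region_lengths
    total = config.total_length
    its_sites = np.concatenate([np.arange(l1), np.arange(l1 + l2, total)])
    ancestor = rng_refs.choice(BASES, size=total)

    per_site = config.interspecies_divergence / 2.0  # star phylogeny branch rate
    min_diffs = int(np.ceil(config.min_interspecies_divergence * len(its_sites)))
    refs: list[np.ndarray] = []
    ref_matrix: list[np.ndarray] = []
    while len(refs) < config.n_true_otus:
        mask = rng_refs.random(len(its_sites)) < per_site
        cand = _mutate(ancestor, its_sites[mask], rng_refs)
        cand_its = cand[its_sites]
        if ref_matrix:
            dists = (np.stack(ref_matrix) != cand_its).sum(axis=1)
            if dists.min() < min_diffs:
                continue
        refs.append(cand)
        ref_matrix.append(cand_its)

    otu_ids = [f"OTU{i:03d}" for i in range(1, config.n_true_otus + 1)]
    rows = []
    for i, (otu, seq) in enumerate(zip(otu_ids, refs)):
        genus = i // config.otus_per_genus
        family = genus // config.genera_per_family
        rows.append(
            {
                "otu_id": otu,
                "sequence": _to_str(seq),
                "species": f"species_{i + 1:03d}",
                "genus": f"genus_{genus + 1:02d}",
                "family": f"family_{family + 1:02d}",
                "its1_end": l1,
                "fivep8s_end": l1 + l2,
            }
        )
    references = pd.DataFrame(rows)

    # Within-OTU variants: three genotypes at pairwise Hamming distance
    # exactly 3 (reference, and the same 3 ITS positions switched to two
    # different alternative bases), within the intraspecies divergence cap.
    variants: dict[str, list[str]] = {}
    n_poly = min(3, int(config.intraspecies_divergence * total))
    for otu, seq in zip(otu_ids, refs):
        if n_poly < 3:
            variants[otu] = [_to_str(seq)]
            continue
        pos = rng_refs.choice(its_sites, size=3, replace=False)
        v1, v2 = seq.copy(), seq.copy()
        for p in pos:
            alts = BASES[BASES != seq[p]]
            a1, a2 = rng_refs.choice(alts, size=2, replace=False)
            v1[p], v2[p] = a1, a2
        variants[otu] = [_to_str(seq), _to_str(v1), _to_str(v2)]

    if config.abundance_model == "lognormal":
        ab = rng_refs.lognormal(mean=0.0, sigma=config.abundance_sdlog, size=len(otu_ids))
    else:  # logseries: geometric-like long tail via exponential ranks
        ranks = rng_refs.permutation(len(otu_ids)) + 1
        ab = np.exp(-ranks / config.logseries_alpha) / ranks
    abundance = dict(zip(otu_ids, ab))

    pools = _partition_pools(otu_ids, config, rng_pools)
    return Metacommunity(config, references, variants, abundance, pools)


@dataclass
class _RootSystemSampler:
    """Draws clone templates for one root system."""

    community: Metacommunity
    root_system: str
    rng: np.random.Generator
    variant_choice: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        cfg = self.community.config
        pools = self.community.pools[self.root_system]
        f_priv, f_sub, f_main = cfg.turnover
        f_global = max(0.0, 1.0 - f_priv - f_sub - f_main)
        weights = dict(zip(_POOL_LEVELS, (f_priv, f_sub, f_main, f_global)))
        # drop empty pools and renormalise
        levels = [lv for lv in _POOL_LEVELS if pools[lv] and weights[lv] > 0]
        if not levels:
            levels = [lv for lv in _POOL_LEVELS if pools[lv]]
            probs = np.ones(len(levels))
        else:
            probs = np.array([weights[lv] for lv in levels])
        if not levels:
            raise ValueError(f"no non-empty OTU pool for {self.root_system}")
        self._levels = levels
        self._level_probs = probs / probs.sum()
        self._pool_otus = {
            lv: list(pools[lv]) for lv in levels
        }
        self._pool_weights = {
            lv: np.array([self.community.abundance[o] for o in self._pool_otus[lv]])
            for lv in levels
        }

    def draw_otu(self) -> str:
        lv = self._levels[self.rng.choice(len(self._levels), p=self._level_probs)]
        w = self._pool_weights[lv]
        idx = self.rng.choice(len(w), p=w / w.sum())
        return self._pool_otus[lv][idx]

    def draw_genotype(self, otu: str) -> tuple[str, int]:
        """Pick a genotype variant; the variant subset is fixed per (root
        system, OTU) on first use (1-3 variants)."""
        cfg = self.community.config
        available = self.community.variants[otu]
        if otu not in self.variant_choice:
            n_var = 1 + self.rng.choice(3, p=np.array(cfg.variant_count_probs))
            n_var = min(n_var, len(available))
            chosen = sorted(self.rng.choice(len(available), size=n_var, replace=False))
            self.variant_choice[otu] = [int(c) for c in chosen]
        vidx = self.variant_choice[otu][
            self.rng.choice(len(self.variant_choice[otu]))
        ]
        return available[vidx], vidx


def sample_clone_library(
    community: Metacommunity, config: SimulationConfig | None = None
) -> tuple[list[CloneRecord], SimulationTruth]:
    """Sample the clone library and its ground truth.

    Each root system yields exactly ``clones_per_root_system`` authentic
    clones; with ``replace_chimeras`` (the default, mirroring how chimaeric
    clones were substituted with newly sequenced ones in the emulated
    workflow) chimaeric clones are emitted *in addition* to the authentic
    quota, otherwise they count against it.  Chimeras join the ITS1 of one
    sampled template to the 5.8S+ITS2 of a template from a different OTU.
    PCR errors are i.i.d. per-base substitutions applied to every clone.
    """
    config = config or community.config
    if config.region_lengths != community.config.region_lengths:
        raise ValueError("config incompatible with the generated community")
    ss = np.random.SeedSequence(config.seed)
    _, _, rng_sample = [np.random.default_rng(s) for s in ss.spawn(3)]

    its1_end, fivep8s_end = community.region_bounds()
    total = config.total_length
    records: list[CloneRecord] = []
    truth_rows: list[dict] = []
    hier = config.hierarchy()

    for _, row in hier.iterrows():
        rs = row["root_system"]
        sampler = _RootSystemSampler(community, rs, rng_sample)
        n_authentic = 0
        clone_no = 0
        while n_authentic < config.clones_per_root_system:
            clone_no += 1
            otu = sampler.draw_otu()
            seq_str, vidx = sampler.draw_genotype(otu)
            seq = np.frombuffer(seq_str.encode(), dtype=np.uint8).copy()
            is_chimera = rng_sample.random() < config.chimera_rate
            parent2 = ""
            breakpoint_pos = -1
            if is_chimera:
                otu2 = otu
                while otu2 == otu:
                    otu2 = sampler.draw_otu()
                seq2_str, vidx2 = sampler.draw_genotype(otu2)
                seq2 = np.frombuffer(seq2_str.encode(), dtype=np.uint8)
                if config.chimera_breakpoint == "junction":
                    breakpoint_pos = its1_end
                else:
                    breakpoint_pos = int(rng_sample.integers(1, total))
                seq = np.concatenate([seq[:breakpoint_pos], seq2[breakpoint_pos:]])
                parent2 = f"{otu2}.v{vidx2}"
            err_mask = rng_sample.random(total) < config.pcr_error_rate
            err_pos = np.nonzero(err_mask)[0]
            if err_pos.size:
                seq = _mutate(seq, err_pos, rng_sample)
            clone_id = (
                f"{row['main_locality']}_{row['sub_locality']}_{rs}_c{clone_no:02d}"
            )
            records.append(
                CloneRecord(
                    id=clone_id,
                    sequence=_to_str(seq),
                    root_system=rs,
                    sub_locality=row["sub_locality"],
                    main_locality=row["main_locality"],
                    region_bounds=(its1_end, fivep8s_end),
                )
            )
            counts_toward_quota = (not is_chimera) or (not config.replace_chimeras)
            if counts_toward_quota:
                n_authentic += 1
            truth_rows.append(
                {
                    "clone_id": clone_id,
                    "root_system": rs,
                    "sub_locality": row["sub_locality"],
                    "main_locality": row["main_locality"],
                    "otu": otu,
                    "genotype": f"{otu}.v{vidx}",
                    "is_chimera": bool(is_chimera),
                    "parent1": f"{otu}.v{vidx}" if is_chimera else "",
                    "parent2": parent2,
                    "breakpoint": breakpoint_pos,
                    "error_positions": ",".join(str(p) for p in err_pos),
                }
            )
    truth = SimulationTruth(pd.DataFrame(truth_rows), community)
    return records, truth


def simulate_library(
    config: SimulationConfig | None = None,
) -> tuple[list[CloneRecord], SimulationTruth]:
    """Convenience wrapper: generate the community and sample from it."""
    config = config or SimulationConfig()
    community = generate_metacommunity(config)
    return sample_clone_library(community, config)


def gradient_incidence(
    n_sites: int = 24,
    n_species: int = 80,
    niche_width: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """Single-gradient presence/absence community for ordination validation.

    Species occupy contiguous windows of ``niche_width`` sites around optima
    spread along one gradient, the classic coenocline used to check that CA
    and NMDS recover the same site ordering.  The default width gives about
    one full compositional turnover across the extent, which keeps most
    pairwise dissimilarities below saturation so the site order is actually
    recoverable from ranks.
    """
    rng = np.random.default_rng(seed)
    optima = np.linspace(0, n_sites - 1, n_species) + rng.normal(0, 0.5, n_species)
    sites = np.arange(n_sites)[:, None]
    inc = (np.abs(sites - optima[None, :]) <= niche_width / 2).astype(int)
    keep = inc.sum(axis=0) > 0
    return inc[:, keep]


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain mapping (e.g. parsed YAML), validating keys."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("turnover", "region_lengths", "variant_count_probs"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)
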