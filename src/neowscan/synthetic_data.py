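"""Simulator for a ZW clade with known sex-autosome fusion truth.

The generator emulates the statistical structure that the fusion scan
exploits in a female-heterogametic (ZW) clade whose females are achiasmatic
(no crossing over in female meiosis):

* a neutral background panel per species: biallelic sites at uniform random
  positions, ancestral allele frequencies from a symmetric Beta(0.5, 0.5)
  prior, perturbed per species by a Balding-Nichols draw with differentiation
  parameter ``theta``; sites are in linkage equilibrium (the fused-haplotype
  private mutations supply all the haplotype structure the genealogy test
  needs);
* a single fused haplotype founded before speciation that is transmitted
  intact matrilineally: it accumulates Poisson(mu * (T_f - T_s) * L) derived
  mutations shared by all clade species, then Poisson(mu * T_s * L)
  species-private mutations per species;
* every female in the fused clade carries exactly one fused haplotype on each
  fused chromosome (plus one background haplotype); males carry two
  background haplotypes;
* Poisson sequencing depth with dosage: depth ~ Poisson(lambda * copies / 2)
  with copies 2 (diploid), 1 (hemizygous Z/W or a degenerated segment) or 0
  (male on a W scaffold);
* segmental mapping dropout: each ``dropout_segment_bp`` block of a fused
  chromosome degenerates with probability ``p_degenerate``; inside it the
  fused haplotype contributes no reads, so females become homozygous for the
  background haplotype at half depth;
* optional hemizygous Z chromosome (females emitted as homozygous diploid
  calls, as a diploid variant caller would) and female-only W scaffolds;
* Hi-C contacts with power-law distance decay and a fusion junction on
  exactly one haplotype, with per-read-pair haplotype tags.

Identical configs (including seed) produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hic import ContactMatrix
from .io_formats import GenotypeTable, MISSING, SampleSheet, write_vcf


@dataclass(frozen=True)
class FusionEvent:
    """A W-autosome fusion: the named chromosome joined the clade's W
    ``age_generations`` generations ago (before speciation)."""

    chrom: str
    age_generations: float


@dataclass
class SimConfig:
    """Study conditions for the simulated clade.

    Defaults describe a two-species clade of 10 females + 10 males per
    species over five 2-Mb autosomes at 30X, with one W-autosome fusion on
    chr4 predating the species split, lepidopteran-scale mutation rate and a
    between-species differentiation of theta = 0.2.
    """

    n_chromosomes: int = 5
    chrom_length_bp: int = 2_000_000
    n_species: int = 2
    samples_per_species_per_sex: int = 10
    n_background_sites_per_chrom: int = 160_000
    mu: float = 2.9e-9
    Ne: float = 1e7
    rec_rate_cM_per_Mb: float = 6.0  # metadata only: achiasmatic females do not recombine
    fusion_events: tuple[FusionEvent, ...] = (FusionEvent("chr4", 2_000_000.0),)
    speciation_age_generations: float = 500_000.0
    fused_clade: tuple[str, ...] | None = None  # default: all species
    balding_nichols_theta: float = 0.2
    depth_lambda: float = 30.0
    dropout_segment_bp: int = 50_000
    p_degenerate: float = 0.05
    phase_switch_rate: float = 0.0
    include_z: bool = False
    z_length_bp: int = 2_000_000
    n_w_scaffolds: int = 0
    w_scaffold_length_bp: int = 100_000
    hic_bin_bp: int = 50_000
    hic_alpha: float = 200.0
    hic_gamma: float = 1.0
    hic_trans_noise: float = 0.5
    hic_tag_rate: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fused_clade is None:
            self.fused_clade = tuple(self.species_names)
        else:
            self.fused_clade = tuple(self.fused_clade)
        for name, v in [
            ("n_chromosomes", self.n_chromosomes),
            ("chrom_length_bp", self.chrom_length_bp),
            ("n_species", self.n_species),
            ("samples_per_species_per_sex", self.samples_per_species_per_sex),
            ("n_background_sites_per_chrom", self.n_background_sites_per_chrom),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu <= 0 or self.Ne <= 0 or self.depth_lambda <= 0:
            raise ValueError("mu, Ne and depth_lambda must be positive")
        if not (0.0 <= self.p_degenerate <= 1.0):
            raise ValueError("p_degenerate must be in [0, 1]")
        if not (0.0 < self.balding_nichols_theta < 1.0):
            raise ValueError("balding_nichols_theta must be in (0, 1)")
        if self.n_background_sites_per_chrom > self.chrom_length_bp:
            raise ValueError("more background sites than base pairs")
        if self.speciation_age_generations < 0:
            raise ValueError("ages must be non-negative")
        for ev in self.fusion_events:
            if ev.age_generations < 0:
                raise ValueError("ages must be non-negative")
            if self.speciation_age_generations > ev.age_generations:
                raise ValueError("speciation must postdate every fusion (T_s < T_f)")
        unknown = set(ev.chrom for ev in self.fusion_events) - set(self.autosome_names)
        if unknown:
            raise ValueError(f"fusion on unknown chromosome(s): {sorted(unknown)}")

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    @property
    def autosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_names(self) -> list[str]:
        names = list(self.autosome_names)
        if self.include_z:
            names.append("chrZ")
        names += [f"W_scaf{i + 1}" for i in range(self.n_w_scaffolds)]
        return names

    def chrom_length(self, chrom: str) -> int:
        if chrom == "chrZ":
            return self.z_length_bp
        if chrom.startswith("W_scaf"):
            return self.w_scaffold_length_bp
        return self.chrom_length_bp

    def to_json(self, path) -> None:
        d = asdict(self)
        d["fusion_events"] = [asdict(ev) for ev in self.fusion_events]
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class SimTruth:
    """Ground-truth labels recorded by the simulator for validation."""

    fused_chroms: list[str]
    fused_clade: tuple[str, ...]
    fused_hap_index: dict[str, dict[str, int]]  # chrom -> sample -> emitted hap column
    degenerate_segments: list[tuple[str, int, int]]  # chrom, start, end (0-based half-open)
    w_scaffolds: list[str]
    shared_private_pos: dict[str, np.ndarray]  # chrom -> positions (1-based)
    species_private_pos: dict[str, dict[str, np.ndarray]]

    def to_json(self, path) -> None:
        d = {
            "fused_chroms": self.fused_chroms,
            "fused_clade": list(self.fused_clade),
            "fused_hap_index": self.fused_hap_index,
            "degenerate_segments": [list(s) for s in self.degenerate_segments],
            "w_scaffolds": self.w_scaffolds,
            "shared_private_pos": {c: v.tolist() for c, v in self.shared_private_pos.items()},
            "species_private_pos": {
                c: {sp: v.tolist() for sp, v in d2.items()}
                for c, d2 in self.species_private_pos.items()
            },
        }
        Path(path).write_text(json.dumps(d))

    def degenerate_mask(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask over 1-based positions falling in degenerated segments."""
        mask = np.zeros(pos.shape[0], dtype=bool)
        for c, start, end in self.degenerate_segments:
            if c == chrom:
                mask |= (pos - 1 >= start) & (pos - 1 < end)
        return mask


@dataclass
class SimulatedDataset:
    table: GenotypeTable
    sheet: SampleSheet
    truth: SimTruth
    config: SimConfig

    def write_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(self.table, out / "genotypes.vcf")
        self.sheet.write(out / "samples.tsv")
        self.truth.to_json(out / "truth.json")
        self.config.to_json(out / "config.json")


# ---------------------------------------------------------------------------
# background panel
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Unfused haplotype pool per species over one chromosome's sites."""

    chrom: str
    positions: np.ndarray  # sorted, 1-based
    ancestral_freq: np.ndarray
    species_freq: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]  # species -> (n_pool, n_sites) int8


def _unique_positions(rng: np.random.Generator, length: int, n: int, taken: np.ndarray | None = None) -> np.ndarray:
    """Draw ``n`` distinct 1-based positions avoiding ``taken``, sorted.

    Rejection sampling: duplicates and collisions are redrawn, so accepted
    positions are uniform over the free sites.
    """
    if n == 0:
        return np.array([], dtype=np.int64)
    avoid = np.array([], dtype=np.int64) if taken is None else np.asarray(taken, dtype=np.int64)
    out = np.array([], dtype=np.int64)
    while out.size < n:
        need = n - out.size
        cand = np.unique(rng.integers(1, length + 1, size=int(need * 1.3) + 16))
        if avoid.size:
            cand = cand[~np.isin(cand, avoid)]
        if out.size:
            cand = cand[~np.isin(cand, out)]
        # np.unique sorted the candidates; shuffle before truncating so the
        # kept subset stays uniform
        cand = rng.permutation(cand)[:need]
        out = np.concatenate([out, cand])
    return np.sort(out)


def simulate_background_panel(
    config: SimConfig,
    chromosome: str,
    rng: np.random.Generator | None = None,
    n_sites: int | None = None,
    pool_size: int | None = None,
) -> HaplotypePanel:
    """Neutral background haplotype pool for one chromosome.

    Ancestral frequencies ~ Beta(0.5, 0.5) (heavy at the extremes, like a
    neutral site-frequency spectrum); species frequencies are Balding-Nichols
    draws Beta(p(1-t)/t, (1-p)(1-t)/t) around the ancestral value; pool
    haplotype alleles are independent Bernoulli draws per site.
    """
    if n_sites is None:
        n_sites = config.n_background_sites_per_chrom
    if n_sites <= 0:
        raise ValueError("zero background sites requested")
    theta = config.balding_nichols_theta
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if pool_size is None:
        # two per diploid sample plus one spare founder candidate
        pool_size = 4 * config.samples_per_species_per_sex + 1
    length = config.chrom_length(chromosome)
    positions = np.sort(rng.choice(length, size=n_sites, replace=False).astype(np.int64) + 1)
    p0 = np.clip(rng.beta(0.5, 0.5, size=n_sites), 1e-3, 1.0 - 1e-3)
    scale = (1.0 - theta) / theta
    species_freq = {}
    haplotypes = {}
    for sp in config.species_names:
        ps = rng.beta(p0 * scale, (1.0 - p0) * scale)
        ps = np.clip(ps, 0.0, 1.0)
        species_freq[sp] = ps
        haplotypes[sp] = (rng.random((pool_size, n_sites)) < ps).astype(np.int8)
    return HaplotypePanel(
        chrom=chromosome,
        positions=positions,
        ancestral_freq=p0,
        species_freq=species_freq,
        haplotypes=haplotypes,
    )


# ---------------------------------------------------------------------------
# fused lineage
# ---------------------------------------------------------------------------


@dataclass
class FusedLineage:
    """The matrilineal fused haplotype over one chromosome.

    Background alleles come from the founder haplotype; ``shared_pos`` are
    derived mutations fixed on the lineage before speciation (heterozygous in
    the females of every clade species) and ``private_pos[sp]`` are mutations
    since speciation, heterozygous in that species' females only.
    """

    founder_species: str
    founder_alleles: np.ndarray  # over the panel's background sites
    shared_pos: np.ndarray
    private_pos: dict[str, np.ndarray]


def simulate_fused_lineage(
    panel: HaplotypePanel,
    t_fusion: float,
    t_speciation: float,
    mu: float,
    length: int,
    species_list: list[str],
    rng: np.random.Generator,
) -> FusedLineage:
    """Accumulate mutations on the non-recombining fused haplotype.

    The founder is one pool haplotype; it gains Poisson(mu (T_f - T_s) L)
    shared derived mutations at new positions, then each species' matriline
    copy gains an independent Poisson(mu T_s L) private mutations.  New sites
    are ancestral (allele 0) on every other haplotype.
    """
    if t_fusion < 0 or t_speciation < 0:
        raise ValueError("ages must be non-negative")
    if t_speciation > t_fusion:
        raise ValueError("speciation must postdate the fusion (T_s <= T_f)")
    founder_species = species_list[0]
    founder_idx = int(rng.integers(panel.haplotypes[founder_species].shape[0]))
    founder = panel.haplotypes[founder_species][founder_idx].copy()

    n_shared = int(rng.poisson(mu * (t_fusion - t_speciation) * length))
    taken = panel.positions
    shared = _unique_positions(rng, length, n_shared, taken)
    taken = np.concatenate([taken, shared])
    private = {}
    for sp in species_list:
        n_priv = int(rng.poisson(mu * t_speciation * length))
        pos = _unique_positions(rng, length, n_priv, taken)
        taken = np.concatenate([taken, pos])
        private[sp] = pos
    return FusedLineage(
        founder_species=founder_species,
        founder_alleles=founder,
        shared_pos=shared,
        private_pos=private,
    )


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------


def _sample_sheet(config: SimConfig) -> SampleSheet:
    rows = []
    for sp in config.species_names:
        for i in range(config.samples_per_species_per_sex):
            rows.append((f"{sp}_F{i + 1:02d}", "female", sp, sp))
        for i in range(config.samples_per_species_per_sex):
            rows.append((f"{sp}_M{i + 1:02d}", "male", sp, sp))
    return SampleSheet(pd.DataFrame(rows, columns=["sample", "sex", "species", "population"]))


def _apply_phase_switches(
    haps: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Swap haplotype columns below random switch points (per sample).

    A switch occurs independently in each inter-site interval with
    probability ``rate``; the swap state is the running parity of switches,
    mimicking phasing switch errors along a chromosome.
    """
    if rate <= 0 or haps.shape[0] < 2:
        return haps
    n_sites, n_samples, _ = haps.shape
    flips = rng.random((n_sites - 1, n_samples)) < rate
    parity = np.zeros((n_sites, n_samples), dtype=bool)
    parity[1:] = np.cumsum(flips, axis=0) % 2 == 1
    out = haps.copy()
    swapped = haps[parity][:, ::-1]
    out[parity] = swapped
    return out


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full genotype/depth/haplotype dataset with truth labels."""
    sheet = _sample_sheet(config)
    clade = tuple(config.fused_clade)
    if config.fusion_events:
        if not any(sheet.select(sex="female", species=clade)):
            raise ValueError("fused clade has no females; fusion unobservable")
    rng = np.random.default_rng(config.seed)
    samples = sheet.samples
    n_samples = len(samples)
    sex = np.array([sheet.frame["sex"].iloc[i] for i in range(n_samples)])
    species_of = np.array([sheet.frame["species"].iloc[i] for i in range(n_samples)])
    fused_by_chrom = {ev.chrom: ev for ev in config.fusion_events}

    chroms_out, pos_out, gt_out, dp_out, hap_out = [], [], [], [], []
    truth = SimTruth(
        fused_chroms=[ev.chrom for ev in config.fusion_events],
        fused_clade=clade,
        fused_hap_index={},
        degenerate_segments=[],
        w_scaffolds=[f"W_scaf{i + 1}" for i in range(config.n_w_scaffolds)],
        shared_private_pos={},
        species_private_pos={},
    )

    for chrom in config.chrom_names:
        length = config.chrom_length(chrom)
        is_w = chrom.startswith("W_scaf")
        is_z = chrom == "chrZ"
        n_bg = (
            config.n_background_sites_per_chrom
            if not is_w
            else max(1, int(round(config.n_background_sites_per_chrom * length / config.chrom_length_bp)))
        )
        panel = simulate_background_panel(config, chrom, rng=rng, n_sites=n_bg)
        lineage = None
        if chrom in fused_by_chrom:
            lineage = simulate_fused_lineage(
                panel,
                fused_by_chrom[chrom].age_generations,
                config.speciation_age_generations,
                config.mu,
                length,
                [sp for sp in config.species_names if sp in clade],
                rng,
            )
            truth.shared_private_pos[chrom] = lineage.shared_pos
            truth.species_private_pos[chrom] = lineage.private_pos

        # merged site list: background + lineage-private sites
        pos = panel.positions
        new_pos = np.array([], dtype=np.int64)
        if lineage is not None:
            new_pos = np.concatenate([lineage.shared_pos] + [lineage.private_pos[sp] for sp in lineage.private_pos])
        all_pos = np.concatenate([pos, new_pos])
        order = np.argsort(all_pos, kind="stable")
        all_pos = all_pos[order]
        n_sites = all_pos.shape[0]
        is_bg = np.concatenate([np.ones(pos.shape[0], bool), np.zeros(new_pos.shape[0], bool)])[order]
        bg_slot = np.full(n_sites, -1, dtype=np.int64)
        bg_slot[is_bg] = np.arange(pos.shape[0])

        # fused haplotype allele per merged site (1 at its own derived sites)
        fused_allele_by_sp = {}
        if lineage is not None:
            base = np.zeros(n_sites, dtype=np.int8)
            base[is_bg] = lineage.founder_alleles
            shared_set = np.isin(all_pos, lineage.shared_pos)
            for sp in lineage.private_pos:
                a = base.copy()
                a[shared_set] = 1
                a[np.isin(all_pos, lineage.private_pos[sp])] = 1
                fused_allele_by_sp[sp] = a

        haps = np.zeros((n_sites, n_samples, 2), dtype=np.int8)
        copies = np.full((n_sites, n_samples), 2, dtype=np.int8)
        pool_cursor = {sp: 0 for sp in config.species_names}

        def next_pool_hap(sp: str) -> np.ndarray:
            i = pool_cursor[sp]
            pool_cursor[sp] += 1
            full = np.zeros(n_sites, dtype=np.int8)
            full[is_bg] = panel.haplotypes[sp][i]
            return full

        for j in range(n_samples):
            sp = species_of[j]
            female = sex[j] == "female"
            if is_w:
                if female:
                    h = next_pool_hap(sp)
                    haps[:, j, 0] = h
                    haps[:, j, 1] = h  # hemizygous, emitted as homozygous diploid
                    copies[:, j] = 1
                else:
                    haps[:, j, :] = MISSING
                    copies[:, j] = 0
            elif is_z and female:
                h = next_pool_hap(sp)
                haps[:, j, 0] = h
                haps[:, j, 1] = h
                copies[:, j] = 1
            elif lineage is not None and female and sp in fused_allele_by_sp:
                fused_col = int(rng.integers(2))
                truth.fused_hap_index.setdefault(chrom, {})[samples[j]] = fused_col
                haps[:, j, 1 - fused_col] = next_pool_hap(sp)
                haps[:, j, fused_col] = fused_allele_by_sp[sp]
            else:
                haps[:, j, 0] = next_pool_hap(sp)
                haps[:, j, 1] = next_pool_hap(sp)

        # segmental degeneration of the fused haplotype (mapping dropout)
        if lineage is not None and config.p_degenerate > 0:
            n_seg = int(np.ceil(length / config.dropout_segment_bp))
            deg = rng.random(n_seg) < config.p_degenerate
            for s in np.flatnonzero(deg):
                start = int(s * config.dropout_segment_bp)
                end = int(min(length, (s + 1) * config.dropout_segment_bp))
                truth.degenerate_segments.append((chrom, start, end))
                in_seg = (all_pos - 1 >= start) & (all_pos - 1 < end)
                for j in range(n_samples):
                    smp = samples[j]
                    if smp in truth.fused_hap_index.get(chrom, {}):
                        fused_col = truth.fused_hap_index[chrom][smp]
                        keep = haps[in_seg, j, 1 - fused_col]
                        haps[in_seg, j, 0] = keep
                        haps[in_seg, j, 1] = keep
                        copies[in_seg, j] = 1

        gt = np.where(
            (haps[:, :, 0] >= 0) & (haps[:, :, 1] >= 0),
            haps[:, :, 0] + haps[:, :, 1],
            MISSING,
        ).astype(np.int8)
        # depth ~ Poisson(lambda * copies / 2); drawn at the diploid rate for
        # everything, then redrawn for the (few) hemizygous or absent cells
        depth = rng.poisson(config.depth_lambda, size=copies.shape).astype(np.int16)
        hemi = copies == 1
        if hemi.any():
            depth[hemi] = rng.poisson(config.depth_lambda / 2.0, size=int(hemi.sum()))
        depth[copies == 0] = 0
        emitted = _apply_phase_switches(haps, config.phase_switch_rate, rng)

        chroms_out.append(np.full(n_sites, chrom, dtype=object))
        pos_out.append(all_pos)
        gt_out.append(gt)
        dp_out.append(depth)
        hap_out.append(emitted)

    n_total = sum(p.shape[0] for p in pos_out)
    table = GenotypeTable(
        chrom=np.concatenate(chroms_out),
        pos=np.concatenate(pos_out),
        ref=np.full(n_total, "A", dtype=object),
        alt=np.full(n_total, "G", dtype=object),
        qual=np.full(n_total, 60.0),
        samples=samples,
        gt=np.concatenate(gt_out, axis=0),
        depth=np.concatenate(dp_out, axis=0),
        haplotypes=np.concatenate(hap_out, axis=0),
    )
    return SimulatedDataset(table=table, sheet=sheet, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------


def _hic_bins(config: SimConfig) -> pd.DataFrame:
    rows = []
    names = list(config.autosome_names) + (["chrZ"] if config.include_z else [])
    for c in names:
        length = config.chrom_length(c)
        start = 0
        while start < length:
            rows.append((c, start, min(start + config.hic_bin_bp, length)))
            start += config.hic_bin_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _molecule_index(config: SimConfig, bins: pd.DataFrame, fused: bool) -> tuple[np.ndarray, np.ndarray]:
    """(molecule id, within-molecule bin coordinate) per bin.

    On the fused haplotype the fused chromosomes are concatenated into one
    molecule in fusion-event order; otherwise every chromosome is its own
    molecule.
    """
    chrom = bins["chrom"].to_numpy()
    mol = np.empty(len(bins), dtype=np.int64)
    coord = np.empty(len(bins), dtype=np.int64)
    fused_order = [ev.chrom for ev in config.fusion_events] if fused else []
    mol_id = 0
    if fused_order:
        offset = 0
        for c in fused_order:
            m = chrom == c
            mol[m] = mol_id
            coord[m] = offset + np.arange(m.sum())
            offset += int(m.sum())
        mol_id += 1
    for c in dict.fromkeys(chrom):
        if c in fused_order:
            continue
        m = chrom == c
        mol[m] = mol_id
        coord[m] = np.arange(m.sum())
        mol_id += 1
    return mol, coord


def simulate_hic(
    config: SimConfig,
    truth: SimTruth,
    haplotype: str,
    rng: np.random.Generator,
) -> ContactMatrix:
    """Contact matrix for one haplotype ('fused' or 'unfused').

    Within a molecule the expected count between bins i, j is
    ``alpha * (1 + d)^-gamma`` with d the within-molecule bin distance;
    between molecules it is the trans-noise floor.  Counts are Poisson.
    """
    if config.hic_gamma <= 0:
        raise ValueError("hic_gamma must be positive")
    if haplotype not in ("fused", "unfused"):
        raise ValueError("haplotype must be 'fused' or 'unfused'")
    bins = _hic_bins(config)
    mol, coord = _molecule_index(config, bins, fused=(haplotype == "fused"))
    n = len(bins)
    same = mol[:, None] == mol[None, :]
    d = np.abs(coord[:, None] - coord[None, :])
    lam = np.where(
        same,
        config.hic_alpha * (1.0 + d) ** (-config.hic_gamma),
        config.hic_trans_noise,
    )
    iu = np.triu_indices(n)
    counts = rng.poisson(lam[iu])
    mat = np.zeros((n, n), dtype=np.int64)
    mat[iu] = counts
    mat = mat + np.triu(mat, 1).T
    return ContactMatrix(matrix=mat, bins=bins)


def simulate_hic_female(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> ContactMatrix:
    """Pooled female matrix = fused + unfused haplotype, with read-pair tags.

    Tags: hap 1 = fused, hap 2 = unfused, hap 0 = unassigned (a Binomial
    ``1 - hic_tag_rate`` thinning of each haplotype's pairs).
    """
    cm_f = simulate_hic(config, truth, "fused", rng)
    cm_u = simulate_hic(config, truth, "unfused", rng)
    pooled = cm_f.matrix + cm_u.matrix
    n = pooled.shape[0]
    iu = np.triu_indices(n)
    rows = []
    for hap_id, cm in ((1, cm_f), (2, cm_u)):
        c = cm.matrix[iu]
        nz = c > 0
        untag = rng.binomial(c[nz], 1.0 - config.hic_tag_rate)
        tagged = c[nz] - untag
        i, j = iu[0][nz], iu[1][nz]
        for arr, h in ((tagged, hap_id), (untag, 0)):
            keep = arr > 0
            if keep.any():
                rows.append(
                    pd.DataFrame(
                        {"bin_i": i[keep], "bin_j": j[keep], "hap": h, "count": arr[keep]}
                    )
                )
    tags = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["bin_i", "bin_j", "hap", "count"])
    )
    tags = tags.sort_values(["bin_i", "bin_j", "hap"], kind="stable").reset_index(drop=True)
    return ContactMatrix(matrix=pooled, bins=cm_f.bins, tags=tags)


def simulate_hic_male(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> ContactMatrix:
    """Male matrix: two unfused copies (males carry no fused haplotype)."""
    cm1 = simulate_hic(config, truth, "unfused", rng)
    cm2 = simulate_hic(config, truth, "unfused", rng)
    return ContactMatrix(matrix=cm1.matrix + cm2.matrix, bins=cm1.bins)
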