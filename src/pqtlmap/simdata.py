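"""Synthetic genetics with a known planted architecture.

This module generates the study conditions the rest of the package is tested
against: a structured panel of inbred strains (population clusters with
block-correlated genotypes, as in a hybrid mouse diversity panel), a
log-abundance matrix in which a cis-driven *mediator* protein propagates a
genetic signal in trans to a co-regulated module of targets, a clinical trait
driven by the module, and an 8-founder diversity-outbred locus whose allele
effects split the founders into a 4-high/4-low pattern.

Because the truth (hotspot markers, mediator identity, module membership,
effect sizes) is returned alongside the data, every downstream stage —
kinship-corrected association, cis/trans classification, hotspot calling,
module construction, mediation — can be scored by recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "ConfigurationError",
    "ArchitectureError",
    "GenotypePanel",
    "HotspotSpec",
    "ArchitectureDesign",
    "PlantedTruth",
    "FounderDosage",
    "DO_FOUNDERS",
    "simulate_panel",
    "plant_architecture",
    "default_design",
    "simulate_trait",
    "simulate_do_locus",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class ArchitectureError(ValueError):
    """A planted architecture that cannot be mapped (e.g. rare hotspot marker)."""


# Diversity Outbred founder strains, conventional order.
DO_FOUNDERS = ("AJ", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")


@dataclass
class GenotypePanel:
    """Homozygous biallelic genotypes for a panel of inbred strains.

    ``alleles`` is strains x markers with entries in {0, 1}; inbred strains
    carry no heterozygous calls, so a single binary dosage per marker suffices.
    Marker positions are 1-based bp, strictly increasing within a chromosome.
    """

    strain_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray

    @property
    def n_strains(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def genotype(self, marker_id: str) -> np.ndarray:
        return self.alleles[:, self.marker_index(marker_id)]

    def maf(self) -> np.ndarray:
        f = self.alleles.mean(axis=0)
        return np.minimum(f, 1.0 - f)


@dataclass
class HotspotSpec:
    """One planted trans-hotspot: a cis-driven mediator fanning out to a module."""

    chrom: str
    n_targets: int
    module_label: str
    b_cis: float = 2.0
    a_t: float = 1.5
    marker_id: str | None = None  # auto-selected on `chrom` when None


@dataclass
class ArchitectureDesign:
    hotspots: list[HotspotSpec]
    n_background: int = 70
    missing_rate: float = 0.10
    min_marker_maf: float = 0.35
    max_marker_r: float = 0.30  # max |r| between auto-selected hotspot markers


@dataclass
class PlantedTruth:
    """Ground truth of a planted architecture, for recovery scoring."""

    hotspot_markers: dict[str, str]  # module label -> marker id
    mediator_ids: dict[str, str]  # module label -> feature id
    module_membership: dict[str, str]  # feature id -> module label
    effect_sizes: dict[str, dict[str, float]]  # label -> {b_cis, a_t}
    trait_gamma: float | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class FounderDosage:
    """Founder-haplotype dosages at a single locus in a multiparent cohort.

    Each row is one (diploid) mouse: 8 entries in [0, 2] summing to 2.
    """

    mouse_ids: list[str]
    dosages: np.ndarray
    founders: tuple[str, ...] = DO_FOUNDERS


def simulate_panel(
    n_strains: int = 72,
    n_markers: int = 2000,
    n_chrom: int = 19,
    n_clusters: int = 6,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    flip_prob: float = 0.25,
    maf_floor: float = 0.05,
) -> GenotypePanel:
    """Simulate a population-structured inbred genotype panel.

    Strains belong to ``n_clusters`` ancestral haplotype groups. For each
    marker an allele frequency is drawn from ``maf_range``, an ancestral allele
    is assigned per cluster, and each strain inherits its cluster's allele with
    per-strain flip probability ``flip_prob``. This produces block-correlated
    genotypes and a kinship matrix with clear within-cluster structure, the
    situation a mixed model must correct for. Markers whose realised minor
    allele frequency falls below ``maf_floor`` are redrawn.
    """
    if n_strains < 1 or n_markers < 1 or n_chrom < 1 or n_clusters < 1:
        raise ConfigurationError("counts must be positive")
    if n_clusters > n_strains:
        raise ConfigurationError("n_clusters must not exceed n_strains")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if not (0.0 <= flip_prob < 0.5):
        raise ConfigurationError("flip_prob must be in [0, 0.5)")

    rng = substream(seed, "panel")
    clusters = np.arange(n_strains) % n_clusters

    def draw(m: int) -> np.ndarray:
        f = rng.uniform(lo, hi, size=m)
        ancestral = rng.random((n_clusters, m)) < f  # cluster x marker
        flips = rng.random((n_strains, m)) < flip_prob
        return (ancestral[clusters, :] ^ flips).astype(np.int8)

    alleles = draw(n_markers)
    for _ in range(200):
        f = alleles.mean(axis=0)
        bad = np.minimum(f, 1 - f) < maf_floor
        if not bad.any():
            break
        alleles[:, bad] = draw(int(bad.sum()))
    else:  # pragma: no cover - pathological floors only
        raise ConfigurationError("could not satisfy the MAF floor; lower maf_floor")

    # Markers spread across chromosomes; positions strictly increasing per chrom.
    per_chrom = np.full(n_chrom, n_markers // n_chrom)
    per_chrom[: n_markers % n_chrom] += 1
    chrom_labels, positions = [], []
    for c in range(n_chrom):
        steps = rng.integers(50_000, 2_000_000, size=per_chrom[c])
        positions.append(3_000_000 + np.cumsum(steps))
        chrom_labels.extend([str(c + 1)] * per_chrom[c])

    return GenotypePanel(
        strain_ids=[f"strain{i:03d}" for i in range(n_strains)],
        marker_ids=[f"m{i:05d}" for i in range(n_markers)],
        chrom=np.asarray(chrom_labels, dtype=object),
        pos_bp=np.concatenate(positions).astype(np.int64),
        alleles=alleles,
    )


def default_design() -> ArchitectureDesign:
    """The default three-hotspot architecture.

    Mirrors the mapped heart-proteome landscape: three trans hotspots on
    chromosomes 13, 17 and 7 fanning out to modules of 26, 22 and 26 proteins
    respectively, each driven through a single cis-regulated mediator.
    """
    return ArchitectureDesign(
        hotspots=[
            HotspotSpec(chrom="13", n_targets=26, module_label="brown"),
            HotspotSpec(chrom="17", n_targets=22, module_label="green"),
            HotspotSpec(chrom="7", n_targets=26, module_label="turquoise"),
        ]
    )


def _select_marker(
    panel: GenotypePanel,
    chrom: str,
    min_maf: float,
    max_r: float,
    taken: list[int],
    rng: np.random.Generator,
) -> int:
    on_chrom = np.flatnonzero(panel.chrom == chrom)
    if on_chrom.size == 0:
        raise ArchitectureError(f"panel has no markers on chromosome {chrom}")
    maf = panel.maf()
    candidates = [int(j) for j in on_chrom if maf[j] >= min_maf]
    G = panel.alleles.astype(float)
    ok = []
    for j in candidates:
        r_ok = True
        for t in taken:
            r = np.corrcoef(G[:, j], G[:, t])[0, 1]
            if abs(r) > max_r:
                r_ok = False
                break
        if r_ok:
            ok.append(j)
    if not ok:
        raise ArchitectureError(
            f"no marker on chromosome {chrom} with MAF >= {min_maf} "
            f"sufficiently independent of previously planted markers"
        )
    return int(rng.choice(ok))


def plant_architecture(
    panel: GenotypePanel,
    design: ArchitectureDesign | None = None,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Plant mediated trans-hotspots into a synthetic abundance matrix.

    For each hotspot the mediator is ``m = b_cis * g + e`` at the hotspot
    marker genotype ``g``, and every module target is ``t = a_t * m + e``:
    all marker-to-target signal flows through the mediator, so targets carry a
    trans association while only the mediator is cis-regulated. Background
    features are pure noise. Feature annotation places each mediator's gene
    within 1 Mb of its hotspot marker and all targets on other chromosomes, so
    the planted cis/trans labels are unambiguous.

    Returns ``(abundance, annotation, truth)`` where abundance is a
    features x strains DataFrame (log-scale, MCAR missingness at the design's
    rate), annotation has columns feature_id/gene_chrom/gene_pos_bp/category,
    and truth records the planted architecture.
    """
    if design is None:
        design = default_design()
    rng = substream(seed, "abundance")
    n = panel.n_strains
    maf = panel.maf()

    marker_idx: list[int] = []
    for hs in design.hotspots:
        if hs.n_targets < 2:
            raise ConfigurationError("module sizes must be >= 2")
        if hs.marker_id is not None:
            j = panel.marker_index(hs.marker_id)
            if maf[j] < design.min_marker_maf:
                raise ArchitectureError(
                    f"hotspot marker {hs.marker_id} has MAF {maf[j]:.3f} below the "
                    f"floor {design.min_marker_maf}; architecture would be unmappable"
                )
        else:
            j = _select_marker(
                panel, hs.chrom, design.min_marker_maf, design.max_marker_r, marker_idx, rng
            )
        marker_idx.append(j)

    all_chroms = list(dict.fromkeys(panel.chrom.tolist()))
    rows, feat_ids, ann_rows = [], [], []
    truth = PlantedTruth(hotspot_markers={}, mediator_ids={}, module_membership={}, effect_sizes={})

    for hs, j in zip(design.hotspots, marker_idx):
        g = panel.alleles[:, j].astype(float)
        mpos = int(panel.pos_bp[j])
        med_id = f"med_{hs.module_label}"
        m = hs.b_cis * g + rng.normal(0.0, noise_sd, n)
        rows.append(m)
        feat_ids.append(med_id)
        gene_pos = max(1, mpos + int(rng.integers(-500_000, 500_001)))
        ann_rows.append((med_id, hs.chrom, gene_pos, hs.module_label))
        other = [c for c in all_chroms if c != hs.chrom]
        for t in range(hs.n_targets):
            tid = f"{hs.module_label}_tgt{t:02d}"
            rows.append(hs.a_t * m + rng.normal(0.0, noise_sd, n))
            feat_ids.append(tid)
            gc = other[t % len(other)]
            ann_rows.append((tid, gc, int(rng.integers(3_000_000, 150_000_000)), hs.module_label))
            truth.module_membership[tid] = hs.module_label
        truth.hotspot_markers[hs.module_label] = panel.marker_ids[j]
        truth.mediator_ids[hs.module_label] = med_id
        truth.module_membership[med_id] = hs.module_label
        truth.effect_sizes[hs.module_label] = {"b_cis": hs.b_cis, "a_t": hs.a_t}

    for b in range(design.n_background):
        bid = f"bg{b:03d}"
        rows.append(rng.normal(0.0, 1.0, n))
        feat_ids.append(bid)
        gc = all_chroms[b % len(all_chroms)]
        ann_rows.append((bid, gc, int(rng.integers(3_000_000, 150_000_000)), "unassigned"))

    X = np.vstack(rows)
    if design.missing_rate > 0:
        mask = rng.random(X.shape) < design.missing_rate
        X = np.where(mask, np.nan, X)
    abundance = pd.DataFrame(X, index=feat_ids, columns=panel.strain_ids)
    annotation = pd.DataFrame(
        ann_rows, columns=["feature_id", "gene_chrom", "gene_pos_bp", "category"]
    ).set_index("feature_id")
    return abundance, annotation, truth


def simulate_trait(
    driver: np.ndarray | pd.Series,
    gamma: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Simulate a strain-level clinical trait driven by ``driver``.

    trait = gamma * standardized(driver) + N(0, noise_sd). The sign of gamma
    controls the direction of the allele-stratified trait difference at the
    locus upstream of the driver (e.g. heart mass decreasing with the allele
    that raises a module eigengene).
    """
    d = np.asarray(pd.Series(driver), dtype=float)
    if d.size == 0:
        raise ConfigurationError("driver must be non-empty")
    sd = d.std()
    if sd == 0:
        raise ConfigurationError("driver is constant; cannot standardize")
    z = (d - d.mean()) / sd
    rng = substream(seed, "trait")
    values = gamma * z + rng.normal(0.0, noise_sd, d.size)
    index = driver.index if isinstance(driver, pd.Series) else pd.RangeIndex(d.size)
    return pd.Series(values, index=index, name="trait")


def simulate_polygenic(
    panel: GenotypePanel, h2: float = 0.5, seed: int = 0
) -> np.ndarray:
    """A heritable null trait: polygenic background, no single causal marker.

    Every marker receives an infinitesimal effect, giving the trait covariance
    proportional to the kinship matrix with heritability ``h2``. No marker has
    an effect large enough to detect individually, so any genome scan of this
    trait is a null scan — but population structure inflates naive regression
    statistics, which is what a mixed model must correct.
    """
    if not (0.0 <= h2 < 1.0):
        raise ConfigurationError("h2 must be in [0, 1)")
    rng = substream(seed, "trait")
    G = panel.alleles.astype(float)
    sd = G.std(axis=0)
    poly = sd > 0
    Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
    u = Z @ rng.normal(0.0, 1.0, poly.sum()) / np.sqrt(poly.sum())
    u *= np.sqrt(h2) / max(u.std(), 1e-12)
    return u + rng.normal(0.0, np.sqrt(1.0 - h2), panel.n_strains)


def four_four_effects(c: float = 0.27) -> np.ndarray:
    """A founder-effect vector splitting the 8 founders 4-high/4-low.

    High: AJ, B6, 129, WSB; low: NOD, NZO, CAST, PWK — the canonical split of
    the heart mt-eQTL hotspot. The default contrast scale ``c`` puts the
    mediator LOD near 50 at n=500 mice with noise_sd=0.5.
    """
    pattern = np.array([+1, +1, +1, -1, -1, -1, -1, +1], dtype=float)  # DO_FOUNDERS order
    return c * pattern


def simulate_do_locus(
    n_mice: int = 500,
    founder_effects: np.ndarray | None = None,
    noise_sd: float = 0.5,
    n_targets: int = 14,
    seed: int = 0,
    target_loading: float = 1.0,
    n_background: int = 30,
) -> tuple[FounderDosage, pd.Series, pd.DataFrame]:
    """Simulate an 8-founder locus acting on targets only through a mediator.

    Each mouse draws two founder haplotypes uniformly at random (a symmetric
    diploid draw), giving an n x 8 dosage matrix with rows summing to 2. The
    mediator is ``dosages @ founder_effects + e``; each of ``n_targets``
    targets is ``target_loading * mediator + e``, plus ``n_background``
    independent noise features as mediation decoys.

    ``founder_effects`` must sum to zero (sum-to-zero contrast coding); a
    non-zero-sum vector is centred with a warning.
    """
    if n_mice < 1:
        raise ConfigurationError("n_mice must be positive")
    e = four_four_effects() if founder_effects is None else np.asarray(founder_effects, float)
    if e.shape != (8,):
        raise ConfigurationError("founder_effects must have length 8")
    if abs(e.sum()) > 1e-10:
        warnings.warn("founder_effects do not sum to zero; centring", stacklevel=2)
        e = e - e.mean()
    rng = substream(seed, "do")
    hap = rng.integers(0, 8, size=(n_mice, 2))
    dosages = np.zeros((n_mice, 8))
    np.add.at(dosages, (np.arange(n_mice), hap[:, 0]), 1.0)
    np.add.at(dosages, (np.arange(n_mice), hap[:, 1]), 1.0)
    mouse_ids = [f"DO{i:04d}" for i in range(n_mice)]

    m = dosages @ e + rng.normal(0.0, noise_sd, n_mice)
    mediator = pd.Series(m, index=mouse_ids, name="mediator")
    feats = {}
    for t in range(n_targets):
        feats[f"target{t:02d}"] = target_loading * m + rng.normal(0.0, noise_sd, n_mice)
    for b in range(n_background):
        feats[f"decoy{b:02d}"] = rng.normal(0.0, 1.0, n_mice)
    targets = pd.DataFrame(feats, index=mouse_ids).T  # features x mice
    return FounderDosage(mouse_ids=mouse_ids, dosages=dosages), mediator, targets
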