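"""Seeded synthetic two-group cohorts with planted regulatory triplets.

The generator emulates the data layout of a small case/control sequencing
study (default n=5 per group): per-sample bisulfite CpG count tables,
miRNA and mRNA raw count matrices, miRNA TSS/strand annotation, miRNA and
3'UTR sequences, and a per-subject clinical trait table.  A configurable
number of regulatory triplets is planted: a differentially methylated
interval inside a miRNA promoter, a shifted miRNA expression mean, and a
counter-shifted target mRNA carrying exact seed-complement sites in its
3'UTR.  The ground truth (which elements were planted, with what signs
and effect sizes) is returned alongside, so downstream detection can be
scored for precision and recall.

Noise models: bisulfite counts are beta-binomial (binomial when the
overdispersion is 0) over Poisson coverage; expression counts are
negative-binomial (gamma-Poisson) with log-normal library-size variation;
clinical traits are normal with group-specific parameters resembling a
small angiography cohort, and the Gensini severity score is generated
with a configurable correlation to the methylation level of the first
planted promoter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError

_DNA = np.frombuffer(b"ACGT", dtype="S1")
_RNA = np.frombuffer(b"ACGU", dtype="S1")

#: Group-specific (mean, sd) for the clinical traits, loosely matching a
#: small angiography cohort; Gensini is generated separately.
TRAIT_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # trait: ((control mean, sd), (case mean, sd))
    "age": ((57.0, 8.15), (66.4, 5.32)),
    "SBP": ((125.0, 10.0), (138.0, 15.0)),
    "DBP": ((75.0, 8.0), (82.0, 10.0)),
    "FPG": ((5.2, 0.6), (6.3, 1.6)),
    "TC": ((2.75, 0.48), (3.97, 0.82)),
    "TG": ((1.26, 1.35), (2.33, 1.47)),
    "LDL-C": ((2.55, 0.51), (3.07, 0.97)),
    "HDL-C": ((1.39, 0.42), (1.02, 0.16)),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    ``meth_delta`` is the planted case-vs-control difference in
    methylation level at planted promoters; ``expr_log2fc`` the planted
    expression effect (miRNA up and target down for 'hypo' triplets, the
    mirror for 'hyper').
    """

    seed: int = 0
    n_case: int = 5
    n_control: int = 5
    n_chroms: int = 4
    chrom_length_bp: int = 1_000_000
    n_mirnas: int = 50
    n_mrnas: int = 200
    n_cpg_per_promoter: int = 8
    n_triplets: int = 5
    meth_base: float = 0.5
    meth_delta: float = 0.4
    meth_direction: str = "hypo"  # 'hypo' | 'hyper' | 'alternate'
    coverage_mean: int = 30
    bb_overdispersion: float = 0.02
    expr_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    library_size_mean: int = 1_000_000
    library_size_cv: float = 0.1
    utr_length_bp: int = 500
    error_rate_p0: float = 0.005
    gensini_meth_r: float = -0.77
    upstream_bp: int = 2000
    mirna_length_nt: int = 22
    sites_per_target: int = 2

    def validate(self) -> None:
        for f in ("n_case", "n_control"):
            if getattr(self, f) < 1:
                raise ConfigError(f, "must be >= 1")
        for f in ("n_chroms", "chrom_length_bp", "n_mirnas", "n_mrnas",
                  "n_cpg_per_promoter", "coverage_mean", "library_size_mean",
                  "utr_length_bp", "upstream_bp", "mirna_length_nt"):
            if getattr(self, f) <= 0:
                raise ConfigError(f, "must be positive")
        if self.n_triplets < 0:
            raise ConfigError("n_triplets", "must be nonnegative")
        if self.n_triplets > min(self.n_mirnas, self.n_mrnas):
            raise ConfigError(
                "n_triplets", "cannot exceed min(n_mirnas, n_mrnas)"
            )
        if not 0 < self.meth_base < 1:
            raise ConfigError("meth_base", "must lie in (0,1)")
        if self.meth_delta < 0:
            raise ConfigError("meth_delta", "must be nonnegative")
        need_low = self.meth_direction in ("hypo", "alternate")
        need_high = self.meth_direction in ("hyper", "alternate")
        if need_low and self.meth_base - self.meth_delta < 0:
            raise ConfigError("meth_delta", "meth_base - meth_delta below 0")
        if need_high and self.meth_base + self.meth_delta > 1:
            raise ConfigError("meth_delta", "meth_base + meth_delta above 1")
        if self.meth_direction not in ("hypo", "hyper", "alternate"):
            raise ConfigError("meth_direction", "must be hypo|hyper|alternate")
        if self.bb_overdispersion < 0 or self.bb_overdispersion >= 1:
            raise ConfigError("bb_overdispersion", "must lie in [0,1)")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion", "must be nonnegative")
        if not 0 < self.error_rate_p0 < 1:
            raise ConfigError("error_rate_p0", "must lie in (0,1)")
        if not -1 <= self.gensini_meth_r <= 1:
            raise ConfigError("gensini_meth_r", "must lie in [-1,1]")
        if self.mirna_length_nt < 8:
            raise ConfigError("mirna_length_nt", "must be >= 8")


@dataclass(frozen=True)
class PlantedTriplet:
    """One planted DMR -> miRNA -> target-mRNA chain with its signs."""

    dmr_chrom: str
    dmr_start: int
    dmr_end: int
    mirna_id: str
    mrna_id: str
    meth_direction: str  # 'hypo' | 'hyper' (in cases)
    mirna_direction: str  # 'up' | 'down'
    mrna_direction: str  # 'up' | 'down'
    meth_delta: float
    mirna_log2fc: float
    mrna_log2fc: float


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort."""

    triplets: list[PlantedTriplet] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"triplets": [asdict(t) for t in self.triplets]}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SynthTruth":
        data = json.loads(text)
        return cls(triplets=[PlantedTriplet(**t) for t in data["triplets"]])


@dataclass
class CohortBundle:
    """All tables of one synthetic cohort, keyed by consistent sample ids."""

    config: SynthConfig
    samples: pd.DataFrame  # sample_id, group
    cpg: pd.DataFrame  # chrom, pos, strand, m_<s>, u_<s> ...
    mirna_counts: pd.DataFrame
    mrna_counts: pd.DataFrame
    mirna_annotation: pd.DataFrame  # mirna_id, chrom, tss, strand
    mrna_annotation: pd.DataFrame  # mrna_id, exon_length_bp
    mirna_sequences: dict[str, str]
    utr_sequences: dict[str, str]
    clinical: pd.DataFrame  # index sample_id; trait columns + group
    chrom_lengths: dict[str, int]
    truth: SynthTruth

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["group"]))

    @property
    def case_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == "case", "sample_id"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == "control", "sample_id"])

    def cpg_group_table(self, group: str) -> pd.DataFrame:
        """Wide CpG table restricted to one group's sample columns."""
        ids = self.case_samples if group == "case" else self.control_samples
        cols = ["chrom", "pos", "strand"]
        cols += [f"m_{s}" for s in ids] + [f"u_{s}" for s in ids]
        return self.cpg[cols]


def _random_seq(rng: np.random.Generator, n: int, alphabet: np.ndarray) -> str:
    return rng.choice(alphabet, size=n).tobytes().decode("ascii")


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, level: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial counts with mean n*level and intra-class rho."""
    level = np.broadcast_to(level, n.shape)
    if rho <= 0:
        return rng.binomial(n, level)
    a = level * (1 - rho) / rho
    b = (1 - level) * (1 - rho) / rho
    # guard exact 0/1 levels where the beta is degenerate
    p = np.where(
        (level <= 0) | (level >= 1),
        level,
        rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)),
    )
    return rng.binomial(n, p)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, disp: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts: var = mu + disp*mu^2."""
    if disp <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
    return rng.poisson(lam)


def _scrub_sites(
    rng: np.random.Generator, utr: str, sites: list[str], max_rounds: int = 50
) -> str:
    """Mutate away every occurrence of the given sites in a UTR."""
    seq = list(utr)
    for _ in range(max_rounds):
        text = "".join(seq)
        hit = False
        for site in sites:
            at = text.find(site)
            while at != -1:
                hit = True
                mid = at + len(site) // 2
                choices = [b for b in "ACGT" if b != seq[mid]]
                seq[mid] = choices[int(rng.integers(len(choices)))]
                text = "".join(seq)
                at = text.find(site)
        if not hit:
            break
    return "".join(seq)


def _seed_site_dna(mirna_seq: str) -> str:
    """DNA reverse complement of miRNA positions 2-8 (the 7mer-m8 site)."""
    seed = mirna_seq[1:8].replace("U", "T").replace("u", "t").upper()
    return str(Seq(seed).reverse_complement())


def generate_cohort(config: SynthConfig) -> CohortBundle:
    """Generate a complete cohort; deterministic for a given config.

    Planted triplets carry an expected case-vs-control methylation
    difference of ``meth_delta`` at their promoter CpGs and expression
    log2 fold changes of +/- ``expr_log2fc`` with sign-consistent
    directions (hypomethylated promoter -> up miRNA -> down target, or
    the mirror for hypermethylated).  Non-planted features are null.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    case_ids = [f"A{i}" for i in range(config.n_case)]
    control_ids = [f"N{i}" for i in range(config.n_control)]
    sample_ids = case_ids + control_ids
    samples = pd.DataFrame(
        {"sample_id": sample_ids,
         "group": ["case"] * len(case_ids) + ["control"] * len(control_ids)}
    )

    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chroms)
    }
    chrom_names = list(chrom_lengths)

    # --- miRNA placement: TSSs evenly spaced, random strands -------------
    mirna_ids = [f"miR-{i + 1}" for i in range(config.n_mirnas)]
    per_chrom = int(np.ceil(config.n_mirnas / config.n_chroms))
    spacing = config.chrom_length_bp // (per_chrom + 1)
    if spacing <= config.upstream_bp:
        raise ConfigError(
            "chrom_length_bp",
            "too short to place miRNA promoters without overlap; "
            "increase length or reduce n_mirnas",
        )
    chroms, tsss = [], []
    for i in range(config.n_mirnas):
        chroms.append(chrom_names[i % config.n_chroms])
        slot = i // config.n_chroms
        tsss.append(spacing * (slot + 1))
    strands = rng.choice(np.array(["+", "-"]), size=config.n_mirnas)
    mirna_annotation = pd.DataFrame(
        {"mirna_id": mirna_ids, "chrom": chroms, "tss": tsss, "strand": strands}
    )

    # promoter interval on the forward axis (strand-aware upstream window)
    prom_start = np.where(
        strands == "+",
        np.maximum(0, np.array(tsss) - config.upstream_bp),
        np.array(tsss),
    )
    prom_end = np.where(
        strands == "+",
        np.array(tsss),
        np.minimum(config.chrom_length_bp, np.array(tsss) + config.upstream_bp),
    )

    # --- planted triplets ------------------------------------------------
    planted_mirna_idx = rng.choice(
        config.n_mirnas, size=config.n_triplets, replace=False
    )
    mrna_ids = [f"GENE{i + 1}" for i in range(config.n_mrnas)]
    planted_mrna_idx = rng.choice(
        config.n_mrnas, size=config.n_triplets, replace=False
    )
    directions = []
    for k in range(config.n_triplets):
        if config.meth_direction == "alternate":
            directions.append("hypo" if k % 2 == 0 else "hyper")
        else:
            directions.append(config.meth_direction)

    # --- CpG positions and methylation counts ----------------------------
    cpg_rows = []
    site_levels_case, site_levels_ctrl = [], []
    planted_site_idx: dict[int, np.ndarray] = {}
    meth_dir_by_mirna = {
        int(mi): d for mi, d in zip(planted_mirna_idx, directions)
    }
    n_sites_total = 0
    for j in range(config.n_mirnas):
        span = int(prom_end[j] - prom_start[j])
        n_cpg = min(config.n_cpg_per_promoter, span)
        pos = np.sort(
            rng.choice(span, size=n_cpg, replace=False) + int(prom_start[j])
        )
        lv_case = np.full(n_cpg, config.meth_base)
        lv_ctrl = np.full(n_cpg, config.meth_base)
        if j in meth_dir_by_mirna:
            if meth_dir_by_mirna[j] == "hypo":
                lv_case = np.full(n_cpg, config.meth_base - config.meth_delta)
            else:
                lv_case = np.full(n_cpg, config.meth_base + config.meth_delta)
            planted_site_idx[j] = np.arange(n_sites_total, n_sites_total + n_cpg)
        for p in pos:
            cpg_rows.append((chroms[j], int(p), "+"))
        site_levels_case.append(lv_case)
        site_levels_ctrl.append(lv_ctrl)
        n_sites_total += n_cpg

    cpg = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "strand"])
    lv_case = np.concatenate(site_levels_case) if site_levels_case else np.empty(0)
    lv_ctrl = np.concatenate(site_levels_ctrl) if site_levels_ctrl else np.empty(0)
    for s in sample_ids:
        level = lv_case if s in case_ids else lv_ctrl
        cov = rng.poisson(config.coverage_mean, size=len(cpg))
        m = _beta_binomial(rng, cov, level, config.bb_overdispersion)
        cpg[f"m_{s}"] = m
        cpg[f"u_{s}"] = cov - m
    cpg = cpg.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # --- expression -------------------------------------------------------
    lib_sigma = np.sqrt(np.log1p(config.library_size_cv**2))

    def _counts(n_feat, planted_idx, planted_lfc_sign, length_weight=None):
        # baseline relative abundances span ~2 orders of magnitude;
        # planted features sit in the expressed (upper) half, as a
        # detectably regulated feature must be expressed to begin with
        z = rng.normal(size=n_feat)
        z[np.asarray(planted_idx, dtype=int)] = np.abs(z[np.asarray(planted_idx, dtype=int)])
        rel = np.exp(z)
        if length_weight is not None:
            rel = rel * length_weight
        rel = rel / rel.sum()
        fc = np.ones(n_feat)
        for idx, sign in zip(planted_idx, planted_lfc_sign):
            fc[idx] = 2.0 ** (sign * config.expr_log2fc)
        counts = {}
        for s in sample_ids:
            lib = rng.lognormal(np.log(config.library_size_mean), lib_sigma)
            mu = rel * lib * (fc if s in case_ids else 1.0)
            counts[s] = _nb_counts(rng, mu, config.nb_dispersion)
        return pd.DataFrame(counts)

    mirna_signs = [1.0 if d == "hypo" else -1.0 for d in directions]
    mrna_signs = [-s for s in mirna_signs]

    exon_length = rng.integers(500, 5001, size=config.n_mrnas)
    mirna_counts = _counts(config.n_mirnas, planted_mirna_idx, mirna_signs)
    mirna_counts.index = pd.Index(mirna_ids, name="mirna_id")
    mrna_counts = _counts(
        config.n_mrnas, planted_mrna_idx, mrna_signs,
        length_weight=exon_length / 1000.0,
    )
    mrna_counts.index = pd.Index(mrna_ids, name="mrna_id")
    mrna_annotation = pd.DataFrame(
        {"mrna_id": mrna_ids, "exon_length_bp": exon_length.astype(int)}
    )

    # --- sequences --------------------------------------------------------
    mirna_sequences = {
        mid: _random_seq(rng, config.mirna_length_nt, _RNA) for mid in mirna_ids
    }
    utr_sequences = {
        gid: _random_seq(rng, config.utr_length_bp, _DNA) for gid in mrna_ids
    }
    # ground truth must be unambiguous: chance occurrences of a planted
    # miRNA's seed site in any UTR are scrubbed before planting, so the
    # only sites of planted miRNAs are the intended ones
    planted_sites = {
        mirna_ids[mi]: _seed_site_dna(mirna_sequences[mirna_ids[mi]])
        for mi in planted_mirna_idx
    }
    if planted_sites:
        for gid in mrna_ids:
            utr_sequences[gid] = _scrub_sites(
                rng, utr_sequences[gid], list(planted_sites.values())
            )
    for mi, gi in zip(planted_mirna_idx, planted_mrna_idx):
        site = planted_sites[mirna_ids[mi]]
        utr = list(utr_sequences[mrna_ids[gi]])
        n_slots = config.sites_per_target
        usable = config.utr_length_bp - len(site)
        for k in range(n_slots):
            at = int(usable * (k + 1) / (n_slots + 1))
            utr[at:at + len(site)] = site
        utr_sequences[mrna_ids[gi]] = "".join(utr)

    # --- truth ------------------------------------------------------------
    triplets = []
    for (mi, gi, d, ms, gs) in zip(
        planted_mirna_idx, planted_mrna_idx, directions, mirna_signs, mrna_signs
    ):
        sites = planted_site_idx[int(mi)]
        pos = [cpg_rows[i][1] for i in sites]  # pre-sort order indices
        triplets.append(
            PlantedTriplet(
                dmr_chrom=chroms[mi],
                dmr_start=int(min(pos)),
                dmr_end=int(max(pos)) + 1,
                mirna_id=mirna_ids[mi],
                mrna_id=mrna_ids[gi],
                meth_direction=d,
                mirna_direction="up" if ms > 0 else "down",
                mrna_direction="up" if gs > 0 else "down",
                meth_delta=config.meth_delta,
                mirna_log2fc=ms * config.expr_log2fc,
                mrna_log2fc=gs * config.expr_log2fc,
            )
        )
    truth = SynthTruth(triplets=triplets)

    # --- clinical traits --------------------------------------------------
    clinical = _clinical_table(rng, config, samples, truth, cpg, case_ids)

    return CohortBundle(
        config=config, samples=samples, cpg=cpg,
        mirna_counts=mirna_counts, mrna_counts=mrna_counts,
        mirna_annotation=mirna_annotation, mrna_annotation=mrna_annotation,
        mirna_sequences=mirna_sequences, utr_sequences=utr_sequences,
        clinical=clinical, chrom_lengths=chrom_lengths, truth=truth,
    )


def _clinical_table(
    rng: np.random.Generator,
    config: SynthConfig,
    samples: pd.DataFrame,
    truth: SynthTruth,
    cpg: pd.DataFrame,
    case_ids: list[str],
) -> pd.DataFrame:
    is_case = samples["group"].to_numpy() == "case"
    data: dict[str, np.ndarray] = {}
    for trait, ((mc, sc), (ma, sa)) in TRAIT_PARAMS.items():
        vals = np.where(
            is_case,
            rng.normal(ma, sa, size=len(samples)),
            rng.normal(mc, sc, size=len(samples)),
        )
        if trait in ("TC", "TG", "LDL-C", "HDL-C", "FPG"):
            vals = np.maximum(vals, 0.1)
        data[trait] = np.round(vals, 2)

    # Gensini correlated with the first planted promoter's methylation
    noise = rng.normal(size=len(samples))
    if truth.triplets:
        t = truth.triplets[0]
        mask = (
            (cpg["chrom"] == t.dmr_chrom)
            & (cpg["pos"] >= t.dmr_start)
            & (cpg["pos"] < t.dmr_end)
        )
        sub = cpg[mask]
        meth = np.array(
            [
                sub[f"m_{s}"].sum() / max(sub[f"m_{s}"].sum() + sub[f"u_{s}"].sum(), 1)
                for s in samples["sample_id"]
            ]
        )
        z = (meth - meth.mean()) / (meth.std() or 1.0)
        r = config.gensini_meth_r
        g = r * z + np.sqrt(max(1 - r**2, 0.0)) * noise
    else:
        g = noise
    data["Gensini"] = np.round(np.maximum(30.0 + 25.0 * g, 0.0), 1)

    clinical = pd.DataFrame(data, index=samples["sample_id"])
    clinical.insert(0, "group", samples["group"].to_numpy())
    clinical.index.name = "sample_id"
    return clinical


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: CohortBundle, directory: str | Path) -> dict:
    """Write every table of a bundle under ``directory``; return a manifest.

    Layout: per-sample CpG TSVs under ``cpg/``, count matrices and
    annotations as TSV/BED, sequences as FASTA, truth as JSON, and a YAML
    manifest listing each file with its row count.
    """
    directory = Path(directory)
    (directory / "cpg").mkdir(parents=True, exist_ok=True)
    files: dict[str, int] = {}

    for s in bundle.samples["sample_id"]:
        sub = bundle.cpg[["chrom", "pos", "strand", f"m_{s}", f"u_{s}"]].rename(
            columns={f"m_{s}": "m_count", f"u_{s}": "u_count"}
        )
        rel = f"cpg/{s}.tsv"
        sub.to_csv(directory / rel, sep="\t", index=False)
        files[rel] = len(sub)

    bundle.samples.to_csv(directory / "samples.tsv", sep="\t", index=False)
    files["samples.tsv"] = len(bundle.samples)
    bundle.mirna_counts.to_csv(directory / "mirna_counts.tsv", sep="\t")
    files["mirna_counts.tsv"] = len(bundle.mirna_counts)
    bundle.mrna_counts.to_csv(directory / "mrna_counts.tsv", sep="\t")
    files["mrna_counts.tsv"] = len(bundle.mrna_counts)

    bed = bundle.mirna_annotation.copy()
    bed_df = pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["tss"],
            "end": bed["tss"] + 1,
            "name": bed["mirna_id"],
            "score": 0,
            "strand": bed["strand"],
        }
    )
    bed_df.to_csv(directory / "mirna_annotation.bed", sep="\t", index=False,
                  header=False)
    files["mirna_annotation.bed"] = len(bed_df)

    bundle.mrna_annotation.to_csv(directory / "mrna_annotation.tsv", sep="\t",
                                  index=False)
    files["mrna_annotation.tsv"] = len(bundle.mrna_annotation)

    for name, seqs in (
        ("mirna.fasta", bundle.mirna_sequences),
        ("utr.fasta", bundle.utr_sequences),
    ):
        records = [
            SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqs.items()
        ]
        SeqIO.write(records, str(directory / name), "fasta")
        files[name] = len(records)

    bundle.clinical.to_csv(directory / "clinical.tsv", sep="\t")
    files["clinical.tsv"] = len(bundle.clinical)

    chroms = pd.DataFrame(
        {"chrom": list(bundle.chrom_lengths),
         "length": list(bundle.chrom_lengths.values())}
    )
    chroms.to_csv(directory / "chroms.tsv", sep="\t", index=False)
    files["chroms.tsv"] = len(chroms)

    (directory / "truth.json").write_text(bundle.truth.to_json())
    files["truth.json"] = len(bundle.truth.triplets)

    manifest = {
        "config": asdict(bundle.config),
        "files": files,
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def read_bundle(directory: str | Path) -> CohortBundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    config = SynthConfig(**manifest["config"])
    samples = pd.read_csv(directory / "samples.tsv", sep="\t")

    cpg = None
    for s in samples["sample_id"]:
        sub = pd.read_csv(directory / "cpg" / f"{s}.tsv", sep="\t",
                          dtype={"chrom": str})
        sub = sub.rename(columns={"m_count": f"m_{s}", "u_count": f"u_{s}"})
        cpg = sub if cpg is None else cpg.merge(
            sub, on=["chrom", "pos", "strand"], how="inner"
        )

    mirna_counts = pd.read_csv(directory / "mirna_counts.tsv", sep="\t",
                               index_col=0)
    mrna_counts = pd.read_csv(directory / "mrna_counts.tsv", sep="\t",
                              index_col=0)
    bed_path = directory / "mirna_annotation.bed"
    bed_cols = ["chrom", "start", "end", "name", "score", "strand"]
    if bed_path.stat().st_size == 0:
        bed = pd.DataFrame(columns=bed_cols)
    else:
        bed = pd.read_csv(bed_path, sep="\t", header=None, names=bed_cols,
                          dtype={"chrom": str})
    mirna_annotation = pd.DataFrame(
        {"mirna_id": bed["name"], "chrom": bed["chrom"], "tss": bed["start"],
         "strand": bed["strand"]}
    )
    mrna_annotation = pd.read_csv(directory / "mrna_annotation.tsv", sep="\t")
    mirna_sequences = {
        r.id: str(r.seq) for r in SeqIO.parse(str(directory / "mirna.fasta"), "fasta")
    }
    utr_sequences = {
        r.id: str(r.seq) for r in SeqIO.parse(str(directory / "utr.fasta"), "fasta")
    }
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t", index_col=0)
    chroms = pd.read_csv(directory / "chroms.tsv", sep="\t", dtype={"chrom": str})
    chrom_lengths = dict(zip(chroms["chrom"], chroms["length"].astype(int)))
    truth = SynthTruth.from_json((directory / "truth.json").read_text())

    return CohortBundle(
        config=config, samples=samples, cpg=cpg,
        mirna_counts=mirna_counts, mrna_counts=mrna_counts,
        mirna_annotation=mirna_annotation, mrna_annotation=mrna_annotation,
        mirna_sequences=mirna_sequences, utr_sequences=utr_sequences,
        clinical=clinical, chrom_lengths=chrom_lengths, truth=truth,
    )
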