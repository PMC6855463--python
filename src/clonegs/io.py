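"""Readers, writers and the run configuration.

Genotypes move as VCF (GT field mapped to dosages: 0/0 -> -1, 0/1 -> 0,
1/1 -> +1, missing GT -> missing) or as a delimited dosage matrix
(individuals x markers).  Trial tables, clone estimates, kinship matrices
and CV results are plain CSV; variance components and QC reports are
JSON.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ClonalEstimates, GenotypeMatrix, KinshipMatrix

__all__ = [
    "read_genotypes",
    "write_vcf",
    "write_dosage_csv",
    "read_dosage_csv",
    "read_vcf",
    "write_trials",
    "read_trials",
    "write_estimates",
    "write_kinship",
    "read_kinship",
    "RunConfig",
]


# -- genotypes ------------------------------------------------------------

_GT_TO_DOSE = {(0, 0): -1.0, (0, 1): 0.0, (1, 0): 0.0, (1, 1): 1.0}


def read_vcf(path) -> GenotypeMatrix:
    """Read a (possibly bgzipped) VCF into a dosage matrix.

    Multi-allelic records are skipped with a counted warning; duplicate
    sample ids are an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in VCF header")
    rows, meta = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gts = var.genotypes  # [allele_a, allele_b, phased]
        dose = np.empty(len(samples))
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dose[i] = np.nan
            else:
                dose[i] = _GT_TO_DOSE.get((a, b), np.nan)
        rows.append(dose)
        meta.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID or f"{var.CHROM}_{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} multi-allelic records")
    markers = pd.DataFrame(meta)
    return GenotypeMatrix(samples, markers, np.array(rows).T)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal diploid VCF (1-based positions)."""
    dose_to_gt = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonegs\n")
        for chrom in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j, rec in geno.markers.iterrows():
            gts = [
                dose_to_gt.get(d, "./.") if not np.isnan(d) else "./."
                for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{rec['id']}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_dosage_csv(geno: GenotypeMatrix, path) -> None:
    frame = pd.DataFrame(
        geno.dosages, index=geno.samples, columns=geno.markers["id"]
    )
    frame.to_csv(path, index_label="sample")
    Path(str(path) + ".map").write_text(geno.markers.to_csv(index=False))


def read_dosage_csv(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, index_col=0)
    if frame.index.duplicated().any():
        raise ValueError("duplicate sample ids in dosage matrix")
    map_path = Path(str(path) + ".map")
    if map_path.exists():
        markers = pd.read_csv(map_path)
    else:
        markers = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, frame.shape[1] + 1),
                "id": frame.columns,
                "ref": "A",
                "alt": "T",
            }
        )
    return GenotypeMatrix(list(frame.index), markers, frame.to_numpy(float))


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'dosage_csv'; inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".gz" else "dosage_csv"
    if format == "vcf":
        return read_vcf(path)
    if format == "dosage_csv":
        return read_dosage_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# -- tables ---------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_estimates(est: ClonalEstimates, path_csv, path_json=None) -> None:
    est.table.to_csv(path_csv, index=False)
    if path_json:
        Path(path_json).write_text(
            json.dumps(
                {
                    "trait": est.trait,
                    "sigma2_clone": est.sigma2_clone,
                    "sigma2_rep": est.sigma2_rep,
                    "sigma2_resid": est.sigma2_resid,
                    "h2_phen": est.h2_phen,
                    "grand_mean": est.grand_mean,
                    "fixed_effects": {k: float(v) for k, v in est.fixed_effects.items()},
                },
                indent=2,
            )
        )


def write_kinship(km: KinshipMatrix, path) -> None:
    pd.DataFrame(km.values, index=km.samples, columns=km.samples).to_csv(
        path, index_label="id"
    )


def read_kinship(path, kind: str) -> KinshipMatrix:
    frame = pd.read_csv(path, index_col=0)
    return KinshipMatrix(list(frame.index), frame.to_numpy(float), kind=kind)


# -- configuration --------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run settings; defaults are the study's analysis settings."""

    genotype_path: str | None = None
    phenotype_path: str | None = None
    output_dir: str = "clonegs_run"
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    dapc_k: int | str = "auto"
    pc_variance: float = 0.85
    df_variance: float = 0.94
    methods: list = field(default_factory=lambda: ["GBLUP", "RKHS", "RRBLUP"])
    n_iter: int = 10000
    burn_in: int = 2000
    thin: int = 10
    strategies: list = field(default_factory=lambda: ["S1_random"])
    folds: int | None = None
    replicates: int = 3
    traits: list = field(default_factory=list)
    seed: int = 1
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self):
        for name, lo, hi in [
            ("min_call_rate", 0.0, 1.0),
            ("min_maf", 0.0, 0.5),
            ("pc_variance", 0.0, 1.0),
            ("df_variance", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)
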