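"""Readers and writers for the text formats the package exchanges.

Genotypes travel as HapMap text (11 standard header columns, IUPAC
single-letter genotype codes, 1-based positions), as numeric dosage TSV
(taxa rows x marker columns, with a ``.map`` sidecar), or as VCF
(read-only, biallelic SNPs).  Phenotypes, kinship, association results
and benchmark tables are plain TSV/CSV with a provenance comment line.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, ParameterError, PhenotypeVector
from .models import AssocResult
from .structure import KinshipMatrix

logger = logging.getLogger(__name__)

try:
    _VERSION = version("gwasbench")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"

HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_HET_CODE = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}
_CODE_ALLELES = {v: tuple(sorted(k)) for k, v in _HET_CODE.items()}
_CODE_ALLELES.update({b: (b, b) for b in "ACGT"})


def provenance_line(**extra) -> str:
    parts = [f"gwasbench v{_VERSION}"] + [f"{k}={v}" for k, v in extra.items()]
    return "## " + " ".join(parts)


# ---------------------------------------------------------------------------
# genotypes


def _hapmap_call(dosage: int, minor: str, major: str) -> str:
    if dosage == MISSING:
        return "N"
    if dosage == 2:
        return minor
    if dosage == 0:
        return major
    return _HET_CODE[frozenset((minor, major))]


def write_genotypes(geno: GenotypeMatrix, path: str, format: str = "hapmap", **prov) -> None:
    if format == "hapmap":
        _write_hapmap(geno, path, **prov)
    elif format == "dosage_tsv":
        _write_dosage(geno, path, **prov)
    else:
        raise ParameterError(f"unknown genotype format {format!r}")


def _write_hapmap(geno: GenotypeMatrix, path: str, **prov) -> None:
    mm = geno.marker_map
    with open(path, "w") as fh:
        fh.write(provenance_line(**prov) + "\n")
        fh.write("\t".join(HAPMAP_HEADER + list(geno.taxa)) + "\n")
        for j in range(geno.n_markers):
            minor, major = mm["minor"].iat[j], mm["major"].iat[j]
            calls = [_hapmap_call(int(d), minor, major) for d in geno.dosages[:, j]]
            row = [
                mm["id"].iat[j], f"{minor}/{major}", str(mm["chrom"].iat[j]),
                str(int(mm["pos"].iat[j])), "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fh.write("\t".join(row + calls) + "\n")


def _read_hapmap(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("##")]
    if not lines:
        raise ParameterError(f"{path}: empty HapMap file")
    header = lines[0].split("\t")
    if len(header) < 12 or header[0] != "rs#":
        raise ParameterError(f"{path}: line 1: not a HapMap header (11 columns + taxa expected)")
    taxa = header[11:]
    ids, chroms, positions, minors, majors, rows = [], [], [], [], [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        f = line.split("\t")
        if len(f) != 11 + len(taxa):
            raise ParameterError(f"{path}: line {ln_no}: expected {11 + len(taxa)} fields, got {len(f)}")
        try:
            pos = int(f[3])
        except ValueError as exc:
            raise ParameterError(f"{path}: line {ln_no}: non-numeric position {f[3]!r}") from exc
        calls = f[11:]
        alleles: dict[str, int] = {}
        pairs = []
        for ci, call in enumerate(calls):
            pair = _CODE_ALLELES.get(call)
            if pair is None and call not in ("N", "NN", "-"):
                raise ParameterError(
                    f"{path}: line {ln_no}: field {12 + ci}: unknown genotype code {call!r}"
                )
            pairs.append(pair)
            if pair:
                for a in pair:
                    alleles[a] = alleles.get(a, 0) + 1
        declared = f[1].split("/") if "/" in f[1] else []
        for a in declared:
            alleles.setdefault(a, 0)
        if len(alleles) > 2:
            raise ParameterError(f"{path}: line {ln_no}: more than two alleles observed")
        # minor = lower allele count; ties resolved toward the lexicographically
        # smaller letter (same convention as the simulator)
        ordered = sorted(alleles, key=lambda a: (alleles[a], a))
        if not ordered:
            minor = major = "N"
        elif len(ordered) == 1:
            minor = major = ordered[0]
        else:
            minor, major = ordered[0], ordered[1]
        dos = [MISSING if p is None else sum(a == minor for a in p) if minor != major else 0
               for p in pairs]
        ids.append(f[0]); chroms.append(f[2]); positions.append(pos)
        minors.append(minor); majors.append(major); rows.append(dos)
    marker_map = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(positions, dtype=np.int64), "id": ids,
         "minor": minors, "major": majors}
    )
    dosages = np.array(rows, dtype=np.int8).T
    return GenotypeMatrix(dosages, taxa, marker_map)


def _write_dosage(geno: GenotypeMatrix, path: str, **prov) -> None:
    mm = geno.marker_map
    with open(path, "w") as fh:
        fh.write(provenance_line(**prov) + "\n")
        fh.write("\t".join(["taxa"] + list(mm["id"])) + "\n")
        for i, t in enumerate(geno.taxa):
            vals = ["NA" if d == MISSING else str(int(d)) for d in geno.dosages[i]]
            fh.write("\t".join([t] + vals) + "\n")
    mm.to_csv(f"{path}.map", sep="\t", index=False)


def _read_dosage(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("##")]
    if not lines:
        raise ParameterError(f"{path}: empty dosage TSV")
    header = lines[0].split("\t")
    if header[0] != "taxa":
        raise ParameterError(f"{path}: line 1: dosage TSV must start with a 'taxa' column")
    ids = header[1:]
    taxa, rows = [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        f = line.split("\t")
        if len(f) != len(header):
            raise ParameterError(f"{path}: line {ln_no}: expected {len(header)} fields")
        taxa.append(f[0])
        row = np.full(len(ids), MISSING, dtype=np.int8)
        for j, v in enumerate(f[1:]):
            if v not in ("NA", "", "nan"):
                try:
                    row[j] = int(v)
                except ValueError as exc:
                    raise ParameterError(f"{path}: line {ln_no}: bad dosage {v!r}") from exc
        rows.append(row)
    dos = np.vstack(rows)
    import os

    map_path = f"{path}.map"
    if os.path.exists(map_path):
        mm = pd.read_csv(map_path, sep="\t", dtype={"chrom": str, "minor": str, "major": str})
    else:
        mm = pd.DataFrame(
            {"chrom": ["Chr01"] * len(ids), "pos": np.arange(1, len(ids) + 1, dtype=np.int64),
             "id": ids, "minor": ["A"] * len(ids), "major": ["C"] * len(ids)}
        )
    return GenotypeMatrix(dos, taxa, mm)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    taxa = list(vcf.samples)
    ids, chroms, positions, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = var.genotype.array()
        d = gts[:, 0] + gts[:, 1]
        d = np.where((gts[:, 0] < 0) | (gts[:, 1] < 0), MISSING, d)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(d.astype(np.int8))
    if n_skipped:
        logger.warning("read_genotypes(vcf): skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise ParameterError(f"{path}: no biallelic SNP records")
    dos = np.array(rows, dtype=np.int8).T  # ALT dosage
    minors, majors = [], []
    for j in range(dos.shape[1]):
        col = dos[:, j]
        obs = col != MISSING
        f = col[obs].sum() / (2.0 * max(obs.sum(), 1))
        if f > 0.5 or (f == 0.5 and alts[j] > refs[j]):
            col2 = col.copy()
            col2[obs] = 2 - col2[obs]
            dos[:, j] = col2
            minors.append(refs[j]); majors.append(alts[j])
        else:
            minors.append(alts[j]); majors.append(refs[j])
    mm = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(positions, dtype=np.int64), "id": ids,
         "minor": minors, "major": majors}
    )
    return GenotypeMatrix(dos, taxa, mm)


def read_genotypes(path: str, format: str = "hapmap") -> GenotypeMatrix:
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "dosage_tsv":
        return _read_dosage(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ParameterError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotypes


def write_phenotypes(phen: PhenotypeVector | pd.DataFrame, path: str, **prov) -> None:
    if isinstance(phen, PhenotypeVector):
        vals = phen.values if phen.values.ndim == 2 else phen.values[:, None]
        cols = [phen.name] if vals.shape[1] == 1 else [f"{phen.name}_r{i+1}" for i in range(vals.shape[1])]
        df = pd.DataFrame(vals, columns=cols)
        df.insert(0, "Taxa", phen.taxa)
    else:
        df = phen
    with open(path, "w") as fh:
        fh.write(provenance_line(**prov) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=_count_prov_lines(path))
    if "Taxa" not in df.columns:
        raise ParameterError(f"{path}: phenotype TSV must have a 'Taxa' first column")
    return df


def _count_prov_lines(path: str) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                n += 1
            else:
                break
    return n


def align_phenotype(geno: GenotypeMatrix, table: pd.DataFrame, trait: str | None = None
                    ) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Match phenotype rows to genotype taxa by identifier.

    The analysis proceeds on the intersection; dropped taxa are logged.
    An empty intersection is a fatal alignment error.
    """
    trait = trait or table.columns[1]
    lookup = dict(zip(table["Taxa"].astype(str), table[trait]))
    have = [t for t in geno.taxa if t in lookup]
    if not have:
        raise ParameterError("no overlap between phenotype and genotype taxa")
    dropped_g = [t for t in geno.taxa if t not in lookup]
    dropped_p = [t for t in table["Taxa"].astype(str) if t not in set(geno.taxa)]
    if dropped_g or dropped_p:
        logger.warning(
            "taxa alignment: using %d individuals; dropped from genotypes: %s; "
            "dropped from phenotypes: %s", len(have), dropped_g, dropped_p,
        )
    idx = [geno.taxa.index(t) for t in have]
    sub = geno.select_individuals(np.asarray(idx))
    phen = PhenotypeVector(np.array([lookup[t] for t in have], dtype=float), have, name=trait)
    return sub, phen


# ---------------------------------------------------------------------------
# kinship / covariates


def write_kinship(K: KinshipMatrix, path: str, **prov) -> None:
    df = pd.DataFrame(K.values, columns=K.taxa)
    df.insert(0, "Taxa", K.taxa)
    with open(path, "w") as fh:
        fh.write(provenance_line(method=K.method, **prov) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_kinship(path: str, method: str = "VanRaden") -> KinshipMatrix:
    df = pd.read_csv(path, skiprows=_count_prov_lines(path))
    taxa = df["Taxa"].astype(str).tolist()
    vals = df.drop(columns=["Taxa"]).to_numpy(dtype=float)
    return KinshipMatrix(vals, taxa, method)


# ---------------------------------------------------------------------------
# association results / benchmark tables


def write_assoc(result: AssocResult, path: str, **prov) -> None:
    df = result.frame.copy()
    df["model"] = result.model
    with open(path, "w") as fh:
        fh.write(provenance_line(model=result.model, **prov) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    meta = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in result.metadata.items()}
    with open(f"{path}.meta.json", "w") as fh:
        json.dump({"model": result.model, "metadata": meta}, fh, indent=1, default=str)


def read_assoc(path: str) -> AssocResult:
    df = pd.read_csv(path, sep="\t", skiprows=_count_prov_lines(path))
    model = str(df["model"].iat[0]) if "model" in df.columns else "unknown"
    meta = {}
    import os

    if os.path.exists(f"{path}.meta.json"):
        with open(f"{path}.meta.json") as fh:
            meta = json.load(fh).get("metadata", {})
    return AssocResult(df.drop(columns=["model"], errors="ignore"), model, meta)


def write_benchmark(table, path: str, **prov) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(**{**table.provenance, **prov}) + "\n")
        table.cells.to_csv(fh, sep="\t", index=False)


def write_architecture(arch, geno: GenotypeMatrix, path: str, **prov) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(h2=arch.h2_target, n_reps=arch.n_reps, **prov) + "\n")
        arch.to_frame(geno).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_architecture(path: str, geno: GenotypeMatrix, h2: float = 0.5, n_reps: int = 1):
    from .containers import TraitArchitecture

    df = pd.read_csv(path, sep="\t", skiprows=_count_prov_lines(path))
    idx_of = {mid: j for j, mid in enumerate(geno.marker_map["id"])}
    try:
        causal = np.array([idx_of[m] for m in df["id"]], dtype=int)
    except KeyError as exc:
        raise ParameterError(f"architecture marker {exc} not present in the genotype panel")
    return TraitArchitecture(causal, df["effect"].to_numpy(float), h2, n_reps=n_reps)
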