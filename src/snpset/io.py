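"""Readers/writers for summary statistics, genotypes, annotations and
weights, plus window-based SNP-set construction.

Conventions: coordinates are 1-based; gene windows are closed intervals;
summary-statistics tables are tab-delimited with a header row and
configurable column names.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel, GeneSet, SummaryStats, p_to_z, z_to_p

# default column-name candidates, tried case-insensitively
_DEFAULT_COLUMNS = {
    "snp": ("SNP", "ID", "RSID", "MARKER"),
    "chrom": ("CHR", "CHROM", "CHROMOSOME"),
    "pos": ("BP", "POS", "POSITION"),
    "a1": ("A1", "EA", "EFFECT_ALLELE", "ALT"),
    "a2": ("A2", "OA", "OTHER_ALLELE", "REF"),
    "z": ("Z", "ZSCORE", "Z_SCORE"),
    "beta": ("BETA", "B", "EFFECT"),
    "se": ("SE", "STDERR"),
    "p": ("P", "PVAL", "P_VALUE", "PVALUE"),
    "n": ("N", "NMISS", "SAMPLE_SIZE"),
    "maf": ("MAF", "FREQ", "AF"),
}


def _resolve_columns(df: pd.DataFrame, column_map: Optional[dict]) -> dict:
    upper = {c.upper(): c for c in df.columns}
    out = {}
    cmap = column_map or {}
    for role, candidates in _DEFAULT_COLUMNS.items():
        if role in cmap:
            if cmap[role] not in df.columns:
                raise ValueError(f"mapped column {cmap[role]!r} not in file")
            out[role] = cmap[role]
            continue
        for cand in candidates:
            if cand in upper:
                out[role] = upper[cand]
                break
    return out


def read_sumstats(path, column_map: Optional[dict] = None,
                  return_frame: bool = False):
    """Read a tab-delimited summary-statistics table.

    Z is derived as beta/SE when absent; P as 2*Phi(-|Z|) when absent; Z from
    P needs an effect sign (beta).  Rows with non-positive SE are rejected
    with a warning.  Row order is preserved.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = _resolve_columns(df, column_map)
    if "snp" not in cols:
        raise ValueError("summary statistics need a SNP identifier column")
    have_z = "z" in cols
    have_bse = "beta" in cols and "se" in cols
    have_p = "p" in cols
    if not (have_z or have_bse or (have_p and "beta" in cols)):
        raise ValueError(
            "need Z, or BETA+SE, or P with an effect sign to derive Z-scores"
        )
    if have_bse:
        se = pd.to_numeric(df[cols["se"]], errors="coerce")
        bad = ~(se > 0)
        if bad.any():
            warnings.warn(f"rejecting {int(bad.sum())} rows with SE <= 0")
            df = df.loc[~bad.values].reset_index(drop=True)

    if have_z:
        z = pd.to_numeric(df[cols["z"]], errors="coerce").to_numpy()
    elif have_bse:
        z = (
            pd.to_numeric(df[cols["beta"]], errors="coerce")
            / pd.to_numeric(df[cols["se"]], errors="coerce")
        ).to_numpy()
    else:
        p_in = pd.to_numeric(df[cols["p"]], errors="coerce").to_numpy()
        sign = np.sign(pd.to_numeric(df[cols["beta"]], errors="coerce").to_numpy())
        z = p_to_z(p_in, sign=np.where(sign == 0, 1.0, sign))
    p = (
        pd.to_numeric(df[cols["p"]], errors="coerce").to_numpy()
        if have_p
        else z_to_p(z)
    )
    # trust z; re-derive p if the table's values disagree with z
    mism = ~np.isclose(p, z_to_p(z), atol=1e-8)
    if (have_z or have_bse) and mism.any():
        warnings.warn(
            f"{int(mism.sum())} rows had P inconsistent with Z; using 2*Phi(-|Z|)"
        )
        p = z_to_p(z)
    ss = SummaryStats(
        snp_ids=df[cols["snp"]].to_numpy(),
        z=z,
        p=np.clip(p, np.finfo(float).tiny, 1.0),
        n=int(df[cols["n"]].iloc[0]) if "n" in cols else None,
        maf=pd.to_numeric(df[cols["maf"]], errors="coerce").to_numpy()
        if "maf" in cols
        else None,
    )
    return (ss, df, cols) if return_frame else ss


def write_sumstats(ss: SummaryStats, path):
    df = pd.DataFrame({"SNP": ss.snp_ids, "Z": ss.z, "P": ss.p})
    if ss.n is not None:
        df["N"] = ss.n
    if ss.maf is not None:
        df["MAF"] = ss.maf
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, info_path=None) -> GenotypePanel:
    """Read a reference panel from VCF (GT field) or a whitespace-delimited
    dosage matrix with a sidecar SNP-info file (id, chr, pos)."""
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path)
    return _read_matrix(path, info_path)


def _read_vcf(path) -> GenotypePanel:
    from pysam import VariantFile

    ids, chroms, positions, rows = [], [], [], []
    with VariantFile(path) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(f"skipping non-biallelic record at {rec.chrom}:{rec.pos}")
                continue
            dos = []
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(1 for a in gt if a == 1)))
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chroms.append(str(rec.chrom))
            positions.append(rec.pos)
            rows.append(dos)
    if not rows:
        raise ValueError("no usable biallelic records in VCF")
    matrix = np.asarray(rows, dtype=float).T
    return _finalise_panel(matrix, np.array(ids), np.array(positions),
                           np.array(chroms))


def _read_matrix(path, info_path) -> GenotypePanel:
    matrix = np.loadtxt(path, dtype=float)
    matrix = np.atleast_2d(matrix)
    if info_path is None:
        info_path = path + ".info"
    info = pd.read_csv(info_path, sep=r"\s+", header=None,
                       names=["snp", "chrom", "pos"])
    if len(info) != matrix.shape[1]:
        raise ValueError("SNP-info rows do not match matrix columns")
    with np.errstate(invalid="ignore"):
        ok = np.isin(matrix, (0.0, 1.0, 2.0)) | np.isnan(matrix)
    if not ok.all():
        raise ValueError("dosage matrix entries must be 0/1/2 or missing")
    return _finalise_panel(
        matrix,
        info["snp"].to_numpy(),
        info["pos"].to_numpy(),
        info["chrom"].astype(str).to_numpy(),
    )


def _finalise_panel(matrix, ids, positions, chroms) -> GenotypePanel:
    from .datatypes import compute_maf

    all_missing = np.all(np.isnan(matrix), axis=0)
    maf = compute_maf(np.where(np.isnan(matrix), np.nan, matrix))
    keep = ~all_missing & (np.nan_to_num(maf) > 0)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} monomorphic or all-missing SNPs")
    return GenotypePanel(
        matrix=matrix[:, keep],
        snp_ids=ids[keep],
        positions=positions[keep],
        chrom=chroms[keep],
    )


# ---------------------------------------------------------------------------
# annotation and SNP sets
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """4-column text: gene, chr, start, end."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["gene", "chrom", "start", "end"],
                     dtype={"chrom": str})
    first = str(df.iloc[0]["start"])
    if not first.lstrip("-").isdigit():  # header row present
        df = pd.read_csv(path, sep=r"\s+", dtype={1: str})
        df.columns = ["gene", "chrom", "start", "end"]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def build_snp_sets(annotation, snp_source, window_bp: int = 100_000,
                   min_snps: int = 10) -> list[GeneSet]:
    """Assign SNPs to genes by the closed window [start - w, end + w].

    ``snp_source`` may be a GenotypePanel or a DataFrame with columns
    snp/chrom/pos.  Genes with fewer than ``min_snps`` members are dropped;
    the result is independent of annotation row order (sorted by gene id,
    then file order for ties).
    """
    if window_bp < 0:
        raise ValueError("window must be nonnegative")
    if isinstance(snp_source, GenotypePanel):
        snp_df = pd.DataFrame({
            "snp": snp_source.snp_ids,
            "chrom": (snp_source.chrom if snp_source.chrom is not None
                      else np.repeat("1", snp_source.m)),
            "pos": snp_source.positions,
        })
    else:
        snp_df = snp_source.rename(
            columns={c: c.lower() for c in snp_source.columns}
        )
    ann = annotation if isinstance(annotation, pd.DataFrame) else read_annotation(annotation)
    out = []
    for row in ann.sort_values(["gene"], kind="stable").itertuples():
        lo, hi = row.start - window_bp, row.end + window_bp
        sel = (snp_df["chrom"].astype(str) == str(row.chrom)) & \
              (snp_df["pos"] >= lo) & (snp_df["pos"] <= hi)
        ids = snp_df.loc[sel, "snp"].to_numpy()
        if len(ids) >= min_snps:
            out.append(GeneSet(gene_id=str(row.gene), chrom=str(row.chrom),
                               start=int(row.start), end=int(row.end),
                               snp_ids=ids))
    if not out:
        warnings.warn("no gene window captured enough SNPs")
    return out


def harmonize_alleles(sumstats_frame: pd.DataFrame, cols: dict,
                      ref_alleles: pd.DataFrame) -> pd.DataFrame:
    """Align summary-statistic alleles to the reference panel.

    Exact A1/A2 match keeps the sign; a swapped match flips the Z sign;
    strand-ambiguous A/T and C/G SNPs are kept but flagged in the returned
    frame's ``ambiguous`` column.  Unmatched SNPs are dropped.
    """
    df = sumstats_frame.copy()
    if not {"a1", "a2"}.issubset(cols):
        raise ValueError("allele columns required for harmonisation")
    ref = ref_alleles.set_index("snp")
    keep, flip, ambiguous = [], [], []
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for i, row in df.iterrows():
        snp = row[cols["snp"]]
        if snp not in ref.index:
            continue
        a1, a2 = str(row[cols["a1"]]).upper(), str(row[cols["a2"]]).upper()
        r1, r2 = str(ref.loc[snp, "a1"]).upper(), str(ref.loc[snp, "a2"]).upper()
        if (a1, a2) == (r1, r2):
            keep.append(i); flip.append(False)
        elif (a1, a2) == (r2, r1):
            keep.append(i); flip.append(True)
        else:
            continue
        ambiguous.append(comp.get(a1) == a2)
    out = df.loc[keep].copy()
    out["flip"] = flip
    out["ambiguous"] = ambiguous
    return out


def read_weight_file(path) -> pd.DataFrame:
    """Two-column text: snp_id, weight."""
    return pd.read_csv(path, sep=r"\s+", header=None, names=["snp", "weight"])
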