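"""Container and text interchange format for multi-caller genotype tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALLERS = ("gatk", "bcftools", "freebayes")
TRANCHES = ("T1", "T2", "lower")

# genotype codes used throughout
MISSING, HOM_REF, HET, HOM_ALT = -1, 0, 1, 2

GT_TO_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
STR_TO_GT = {v: k for k, v in GT_TO_STR.items()}

#: columns describing a variant, in interchange order
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "impact", "maf", "tranche",
                   "gatk_pass", "bcftools_pass", "freebayes_pass"]


@dataclass
class MultiCallerVariantTable:
    """Variants x samples x callers genotype calls plus variant annotations.

    ``variants`` is indexed by variant_id with the columns in
    :data:`VARIANT_COLUMNS`; ``calls`` is an int8 array of shape
    ``(n_variants, n_samples, 3)`` using the genotype codes above, caller
    axis ordered as :data:`CALLERS`.
    """

    variants: pd.DataFrame
    samples: list = field(default_factory=list)
    calls: np.ndarray = None

    def __post_init__(self):
        if self.calls is None:
            self.calls = np.empty((len(self.variants), 0, 3), dtype=np.int8)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_var, n_samp, n_callers = self.calls.shape
        if n_var != len(self.variants):
            raise ValueError("calls first axis must match the variant table")
        if n_samp != len(self.samples):
            raise ValueError("calls second axis must match the sample list")
        if n_callers != len(CALLERS):
            raise ValueError(f"calls third axis must have {len(CALLERS)} callers")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def to_long(self) -> pd.DataFrame:
        """Flatten to the long TSV dialect (one row per variant/caller/sample)."""
        n_var, n_samp, _ = self.calls.shape
        if n_var == 0 or n_samp == 0:
            cols = (["variant_id"] + VARIANT_COLUMNS[:8]
                    + ["caller", "passed_filter", "sample", "gt"])
            return pd.DataFrame(columns=cols)
        frames = []
        meta = self.variants.reset_index().rename(columns={"index": "variant_id"})
        if "variant_id" not in meta.columns:
            meta = meta.rename(columns={meta.columns[0]: "variant_id"})
        for ci, caller in enumerate(CALLERS):
            gt = self.calls[:, :, ci]
            df = pd.DataFrame(gt, index=self.variant_ids, columns=self.samples)
            df = df.stack().rename("gt_code").reset_index()
            df.columns = ["variant_id", "sample", "gt_code"]
            df["caller"] = caller
            df["passed_filter"] = df["variant_id"].map(
                self.variants[f"{caller}_pass"]).astype(int)
            frames.append(df)
        long = pd.concat(frames, ignore_index=True)
        long = long.merge(
            meta[["variant_id"] + VARIANT_COLUMNS[:8]], on="variant_id", how="left"
        )
        long["gt"] = long["gt_code"].map(GT_TO_STR)
        long = long[["variant_id"] + VARIANT_COLUMNS[:8]
                    + ["caller", "passed_filter", "sample", "gt"]]
        return long.sort_values(["variant_id", "caller", "sample"],
                                kind="stable").reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "MultiCallerVariantTable":
        """Rebuild from the long TSV dialect written by :meth:`to_long`."""
        if long.empty:
            variants = pd.DataFrame(columns=VARIANT_COLUMNS)
            variants.index.name = "variant_id"
            return cls(variants=variants, samples=[],
                       calls=np.empty((0, 0, 3), dtype=np.int8))
        variant_ids = list(dict.fromkeys(long["variant_id"]))
        samples = list(dict.fromkeys(long["sample"]))
        vmeta = (long.drop_duplicates("variant_id")
                 .set_index("variant_id")[VARIANT_COLUMNS[:8]]
                 .loc[variant_ids])
        # per-caller pass flags live on the caller rows
        for caller in CALLERS:
            sub = long[long["caller"] == caller].drop_duplicates("variant_id")
            flags = sub.set_index("variant_id")["passed_filter"].astype(bool)
            vmeta[f"{caller}_pass"] = flags.reindex(variant_ids).fillna(False)
        vidx = {v: i for i, v in enumerate(variant_ids)}
        sidx = {s: i for i, s in enumerate(samples)}
        cidx = {c: i for i, c in enumerate(CALLERS)}
        calls = np.full((len(variant_ids), len(samples), 3), MISSING, dtype=np.int8)
        vi = long["variant_id"].map(vidx).to_numpy()
        si = long["sample"].map(sidx).to_numpy()
        ci = long["caller"].map(cidx).to_numpy()
        calls[vi, si, ci] = long["gt"].map(STR_TO_GT).to_numpy(dtype=np.int8)
        vmeta.index.name = "variant_id"
        vmeta["pos"] = vmeta["pos"].astype(int)
        vmeta["maf"] = vmeta["maf"].astype(float)
        return cls(variants=vmeta, samples=samples, calls=calls)

    def to_tsv(self, path) -> None:
        from ._utils import float_repr

        self.to_long().to_csv(path, sep="\t", index=False, float_format=float_repr)

    @classmethod
    def from_tsv(cls, path) -> "MultiCallerVariantTable":
        long = pd.read_csv(path, sep="\t", comment="#",
                           dtype={"variant_id": str, "sample": str, "chrom": str},
                           float_precision="round_trip")
        return cls.from_long(long)

    def equals(self, other: "MultiCallerVariantTable") -> bool:
        return (
            list(self.samples) == list(other.samples)
            and list(self.variant_ids) == list(other.variant_ids)
            and np.array_equal(self.calls, other.calls)
            and self.variants.reset_index().astype(str).equals(
                other.variants.reset_index().astype(str))
        )
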