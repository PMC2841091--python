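"""On-disk formats: TSV interchange tables, FASTA, BED, YAML config, VCF.

Every pipeline stage reads and writes plain-text tables so stages are
independently re-runnable and diffable:

* intensities — ``array_id  pos  strand  sub_base  intensity``
* calls — ``array_id  pos  ref  call  quality  source  flags``
* truth — ``array_id  pos  genotype  zygosity  alt  is_common`` (+ an
  indel table ``array_id  start  end  seq``)
* design — ``chrom  pos  strand  sub_base  probe_seq  exon_id``
* regions/candidates — BED (0-based half-open)
* reference — FASTA
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import CALL_COLUMNS, N_CALL
from .design import ArrayDesign, BASES, CODE_TO_PAIR
from .indels import IndelCandidate
from .simulate import Indel, SampleIntensities, TruthGenotype

STRANDS = ("fwd", "rev")


# ---- FASTA / BED ----------------------------------------------------------

def read_fasta(path: str | Path) -> tuple[str, str]:
    """First record of a FASTA file as (name, sequence)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()

def write_fasta(name: str, seq: str, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")

def read_bed(path: str | Path) -> list[tuple[int, int, str]]:
    """BED intervals as (start, end, name); names default to exon_<i>."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    out = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"exon_{i:03d}"
        out.append((int(row[1]), int(row[2]), name))
    return out

def write_bed(regions: Sequence[tuple], chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, region in enumerate(regions):
            name = region[2] if len(region) > 2 else f"exon_{i:03d}"
            fh.write(f"{chrom}\t{int(region[0])}\t{int(region[1])}\t{name}\n")


# ---- design ---------------------------------------------------------------

def design_to_frame(design: ArrayDesign) -> pd.DataFrame:
    rows = list(design.iter_features())
    return pd.DataFrame(rows, columns=["pos", "strand", "sub_base", "probe_seq", "exon_id"]).assign(
        chrom=design.chrom
    )[["chrom", "pos", "strand", "sub_base", "probe_seq", "exon_id"]]

def write_design_tsv(design: ArrayDesign, path: str | Path) -> None:
    design_to_frame(design).to_csv(path, sep="\t", index=False)

def read_design_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---- intensities ----------------------------------------------------------

def intensities_to_frame(samples: Sequence[SampleIntensities], design: ArrayDesign) -> pd.DataFrame:
    frames = []
    n = design.n_positions
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "array_id": s.array_id,
                    "pos": np.repeat(design.positions, 8),
                    "strand": np.tile(np.repeat(STRANDS, 4), n),
                    "sub_base": np.tile(list(BASES), 2 * n),
                    "intensity": s.values.reshape(-1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)

def write_intensities_tsv(
    samples: Sequence[SampleIntensities], design: ArrayDesign, path: str | Path
) -> None:
    intensities_to_frame(samples, design).to_csv(path, sep="\t", index=False, float_format="%.6g")

def read_intensities_tsv(path: str | Path, design: ArrayDesign) -> list[SampleIntensities]:
    df = pd.read_csv(path, sep="\t")
    pos_index = pd.Series(np.arange(design.n_positions), index=design.positions)
    out = []
    for array_id, grp in df.groupby("array_id", sort=True):
        values = np.zeros((design.n_positions, 2, 4))
        i = pos_index[grp["pos"]].to_numpy()
        s = (grp["strand"] == "rev").to_numpy().astype(int)
        b = grp["sub_base"].map({base: k for k, base in enumerate(BASES)}).to_numpy()
        values[i, s, b] = grp["intensity"].to_numpy()
        out.append(SampleIntensities(array_id=str(array_id), values=values))
    return out


# ---- calls ----------------------------------------------------------------

def write_calls_tsv(calls: pd.DataFrame | Sequence[pd.DataFrame], path: str | Path) -> None:
    df = calls if isinstance(calls, pd.DataFrame) else pd.concat(calls, ignore_index=True)
    df[CALL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")

def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"flags": str})
    df["flags"] = df["flags"].fillna("")
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed call table, missing columns: {sorted(missing)}")
    return df

def split_batch_calls(calls: pd.DataFrame) -> list[pd.DataFrame]:
    return [grp.reset_index(drop=True) for _, grp in calls.groupby("array_id", sort=True)]


# ---- truth ----------------------------------------------------------------

def truth_to_frame(
    truths: Sequence[TruthGenotype], design: ArrayDesign, array_ids: Sequence[str]
) -> pd.DataFrame:
    frames = []
    for t, aid in zip(truths, array_ids):
        genotype = t.call_string(design)
        frames.append(
            pd.DataFrame(
                {
                    "array_id": aid,
                    "pos": design.positions,
                    "genotype": genotype,
                    "zygosity": t.zygosity,
                    "alt": [BASES[a] if a < 4 else "." for a in t.alt_idx],
                    "is_common": t.is_common.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)

def write_truth_tsv(
    truths: Sequence[TruthGenotype], design: ArrayDesign, array_ids: Sequence[str], path: str | Path
) -> None:
    truth_to_frame(truths, design, array_ids).to_csv(path, sep="\t", index=False)

def write_indels_tsv(
    truths: Sequence[TruthGenotype], array_ids: Sequence[str], path: str | Path
) -> None:
    rows = [
        (aid, ev.start, ev.end, ev.seq or ".")
        for t, aid in zip(truths, array_ids)
        for ev in t.indels
    ]
    pd.DataFrame(rows, columns=["array_id", "start", "end", "seq"]).to_csv(
        path, sep="\t", index=False
    )

def read_truth_tsv(path: str | Path, design: ArrayDesign) -> list[TruthGenotype]:
    df = pd.read_csv(path, sep="\t")
    base_idx = {b: i for i, b in enumerate(BASES)}
    out = []
    for _, grp in df.groupby("array_id", sort=True):
        grp = grp.set_index("pos").loc[design.positions]
        out.append(
            TruthGenotype(
                zygosity=grp["zygosity"].to_numpy(dtype=np.uint8),
                alt_idx=np.array(
                    [base_idx.get(a, 255) for a in grp["alt"]], dtype=np.uint8
                ),
                is_common=grp["is_common"].to_numpy(dtype=bool),
            )
        )
    return out


# ---- indel candidates -----------------------------------------------------

def candidates_to_frame(cands: Sequence[IndelCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.start, c.end, c.evidence, c.n_nocalls, c.n_variants, c.drop_ratio)
            for c in cands
        ],
        columns=["start", "end", "evidence", "n_nocalls", "n_variants", "drop_ratio"],
    )

def write_candidates(
    cands: Sequence[IndelCandidate], chrom: str, tsv_path: str | Path, bed_path: str | Path
) -> None:
    candidates_to_frame(cands).to_csv(tsv_path, sep="\t", index=False)
    write_bed([(c.start, c.end, c.evidence) for c in cands], chrom, bed_path)


# ---- VCF export -----------------------------------------------------------

def calls_to_vcf(calls: pd.DataFrame, design: ArrayDesign, path: str | Path) -> None:
    """Export one array's variant calls (hom-alt and het) as a VCF.

    Positions are written 1-based per VCF convention; quality is the
    caller's log2-ratio score.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={design.chrom},length={len(design.reference)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##INFO=<ID=SRC,Number=1,Type=String,Description="Calling source">')
    array_id = str(calls["array_id"].iloc[0]) if len(calls) else "sample"
    header.add_sample(array_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in calls.iterrows():
            call, ref = str(row["call"]), str(row["ref"])
            if call in (N_CALL, ref):
                continue
            if call in CODE_TO_PAIR:
                alleles = CODE_TO_PAIR[call]
                alts = sorted(alleles - {ref})
                gt = (0, 1) if ref in alleles else (1, 2)
            else:
                alts, gt = [call], (1, 1)
            rec = vcf.new_record(
                contig=design.chrom,
                start=int(row["pos"]),
                alleles=(ref, *alts),
                qual=float(row["quality"]),
            )
            rec.info["SRC"] = str(row["source"])
            rec.samples[array_id]["GT"] = gt
            vcf.write(rec)


# ---- config ---------------------------------------------------------------

def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}

def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
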