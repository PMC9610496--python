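#!/usr/bin/env python
"""Trim, align and count each simulated compartment library.

Reads results/sim/*.fastq, removes the 3' adapter, aligns every read
exhaustively against the transcript reference, and writes per-sample SAM
files plus a combined per-transcript count/RPM table under results/readproc/.
"""

import argparse
from pathlib import Path

import pandas as pd

from rnpfootprint import ReferenceIndex, count_reads, process_fastq, read_transcripts_fasta
from rnpfootprint.readproc import write_sam
from rnpfootprint.synth import DEFAULT_ADAPTER


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/readproc"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    transcripts = read_transcripts_fasta(args.simdir / "reference.fasta")
    index = ReferenceIndex(transcripts)

    all_counts = []
    for fastq in sorted(args.simdir.glob("*.fastq")):
        sample = fastq.stem
        res = process_fastq(fastq, index, DEFAULT_ADAPTER)
        write_sam(args.outdir / f"{sample}.sam", res.alignments, transcripts)
        counts = count_reads(res.alignments)
        counts.insert(0, "sample", sample)
        all_counts.append(counts)
        s = res.stats
        print(f"{sample:10s} reads={s['n_reads']} aligned={s['n_aligned_unique']} "
              f"ambiguous={s['n_ambiguous']} unaligned={s['n_unaligned']} "
              f"too_short={s['n_too_short']}")

    pd.concat(all_counts).to_csv(args.outdir / "counts.tsv", sep="\t", index=False)
    print(f"count table -> {args.outdir / 'counts.tsv'}")


if __name__ == "__main__":
    main()
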