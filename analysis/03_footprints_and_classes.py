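#!/usr/bin/env python
"""Coverage profiles, footprint calls, terminus statistics, classification.

For each compartment library this computes the per-base coverage profile,
calls footprints and matches them against the predicted protected fragments,
measures the 3'-terminus pyrimidine fraction, classifies the profile as
uniform / multi_footprint / core_only, and quantifies each profile's
similarity to the CELL profile.  Outputs: bedGraph tracks, call tables, a
classification report and a coverage figure under results/profiles/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from rnpfootprint import (
    ReferenceIndex,
    classify_profile,
    compute_coverage,
    predict_protected_fragment,
    process_fastq,
    profile_similarity,
    read_protections_bed,
    read_transcripts_fasta,
    terminus_pyrimidine_fraction,
    write_bedgraph,
)
from rnpfootprint.compare import write_classification_tsv
from rnpfootprint.profiles import write_footprints_bed, write_footprints_tsv
from rnpfootprint.synth import DEFAULT_ADAPTER


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/profiles"))
    ap.add_argument("--read-len", type=int, default=50)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    [reference] = read_transcripts_fasta(args.simdir / "reference.fasta")
    annotations = read_protections_bed(args.simdir / "protections.bed")
    index = ReferenceIndex([reference])
    predictions = {a.label: predict_protected_fragment(reference, a)
                   for a in annotations}
    print("predicted protected fragments (1-based):",
          {k: (s + 1, e) for k, (s, e) in predictions.items()})

    profiles, rows = {}, []
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 7))
    for ax, fastq in zip(axes, sorted(args.simdir.glob("*.fastq"))):
        sample = fastq.stem
        res = process_fastq(fastq, index, DEFAULT_ADAPTER)
        profile = compute_coverage(res.alignments, reference)
        profiles[sample] = profile
        write_bedgraph(profile, args.outdir / f"{sample}.depth.bedgraph")
        pc = classify_profile(profile, reference, annotations)
        write_footprints_bed(args.outdir / f"{sample}.calls.bed", reference.id, pc.calls)
        write_footprints_tsv(args.outdir / f"{sample}.calls.tsv", reference.id, pc.calls)
        frac = terminus_pyrimidine_fraction(res.alignments, reference,
                                            read_len=args.read_len)
        rows.append((sample, reference.id, pc))
        print(f"{sample:10s} label={pc.label:16s} breadth={pc.breadth:.3f} "
              f"in_core={pc.in_core_fraction:.3f} "
              f"concordant={pc.n_concordant} pyrimidine_3p={frac:.3f}")

        ax.fill_between(range(len(reference)), profile.depth, step="mid", lw=0)
        ax.set_ylabel(sample, fontsize=8)
        for s, e in predictions.values():
            ax.axvspan(s, e, alpha=0.15, color="red")
    axes[-1].set_xlabel(f"position on {reference.id} (nt)")
    fig.suptitle("coverage by compartment (red: predicted protected fragments)")
    fig.savefig(args.outdir / "coverage.png", dpi=120)

    write_classification_tsv(args.outdir / "classification.tsv", rows)

    if "CELL" in profiles:
        for other in sorted(profiles):
            if other == "CELL":
                continue
            rho = profile_similarity(profiles[other], profiles["CELL"])
            print(f"similarity to CELL: {other:10s} rho={rho:.3f}")


if __name__ == "__main__":
    main()
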