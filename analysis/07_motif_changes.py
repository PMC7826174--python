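"""Scan the two candidate fixed variants for allele-dependent motif changes.

No curated motif database ships with the package, so this driver builds a
small synthetic PFM panel programmatically: one matrix whose consensus
matches the reference-allele window of the candidate SNP (so the alternate
allele must break it), one matching the alternate-allele window (a gain),
and neutral decoys.  It demonstrates the gain/loss calls the pipeline makes
when a real JASPAR file is supplied via the ``pfm_file`` input.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPELINE_CONFIG, save

from cistrans import pipeline as pl
from cistrans.config import FilterConfig
from cistrans.formats_io import PWM


def consensus_pwm(matrix_id, name, consensus, strength=0.9):
    probs = np.full((4, len(consensus)), (1 - strength) / 3)
    for j, b in enumerate(consensus):
        probs["ACGT".index(b), j] = strength
    return PWM(matrix_id, name, probs)


def main() -> None:
    ds = pl.load_dataset(PIPELINE_CONFIG)
    filters = FilterConfig.from_dict(
        {**FilterConfig().to_dict(), **PIPELINE_CONFIG["filters"]})
    snp = ds.variant_sequences[
        ds.variant_sequences["variant_type"] == "SNP"].iloc[0]
    offset = int(snp["variant_offset"])
    seq = snp["reference_sequence"]
    ref_window = seq[offset - 2:offset + 4]  # spans the variant base
    alt_window = (seq[offset - 2:offset] + snp["alt_allele"]
                  + seq[offset + 1:offset + 4])
    pwms = [
        consensus_pwm("SYN0001", "synthetic-ref-match", ref_window),
        consensus_pwm("SYN0002", "synthetic-alt-match", alt_window),
        consensus_pwm("SYN0003", "synthetic-decoy", "ACGTACGT"),
    ]
    tables = pl.stage_motifs(ds, pwms, filters)
    out = tables["motif_changes"]
    path = save(out, "07_motif_changes.tsv")
    changed = out[out["status"] != "unchanged"]
    print(f"{len(changed)} of {len(out)} (variant, motif) pairs change "
          "between alleles:")
    print(out.to_string(index=False))
    print(f"written to {path}")


if __name__ == "__main__":
    main()
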