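"""Adapter trimming and the 16-nt length filter.

Small-RNA inserts are shorter than the sequencer read, so the 3' end runs
into the library adapter; after trimming, fragments shorter than 16 nt are
discarded as unmappable.
"""

from srnascan.config import PipelineConfig
from srnascan.preprocess import ReadRecord, preprocess_reads

ADAPTER = "ATCACCGACTGCCCATAGAGAGG"
reads = [
    ReadRecord("mirna_readthrough", "TGAGGTAGTAGGTTGTATAGTT" + ADAPTER),
    ReadRecord("trf_readthrough", "GCATTGGTGGTTCAGTGGTAGAATTCTCGCC" + ADAPTER[:12]),
    ReadRecord("too_short_after_trim", "ACGTACGTACGT" + ADAPTER),
    ReadRecord("no_adapter", "GGCTGGTCCGATGGTAGTGGGTT"),
]
cfg = PipelineConfig(adapter=ADAPTER)
kept, report = preprocess_reads(reads, cfg, sample_id="demo")

print(f"reads in:              {report.reads_in}")
print(f"adapter trimmed:       {report.reads_trimmed}")
print(f"dropped (<16 nt):      {report.reads_dropped_short}")
print(f"reads out:             {report.reads_out}")
for read in kept:
    print(f"  kept {read.read_id}: {len(read)} nt")
print("A 12-nt insert is discarded: below 16 nt a sequence cannot be placed")
print("confidently against either the ncRNA reference or the genome.")
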