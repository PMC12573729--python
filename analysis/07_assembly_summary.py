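#!/usr/bin/env python
"""Summarize the packaged assembly quality-metrics table.

Reports per-column minima, maxima and means for the twelve symbiont genome
assemblies (span, GC, CDS counts, BUSCO scores, RNA counts).
"""

from pathlib import Path

from wolbshift import report

OUT = Path(__file__).resolve().parents[1] / "results" / "assembly"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    metrics = report.load_assembly_metrics()
    summary = report.summarize_assemblies(metrics)
    summary.to_csv(OUT / "assembly_summary.tsv", sep="\t", index_label="metric")
    print(summary.to_string())
    print(f"\nmean span: {summary.loc['span','mean']:,.0f} bp; "
          f"mean CDS: {summary.loc['n_cds','mean']:.0f}; "
          f"mean GC: {summary.loc['gc','mean']:.3f}")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
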