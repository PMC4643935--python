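"""Quality control: discard out-of-water probe-days and clip to the summer
analysis window (ISO weeks 24-31).

Reads results/data, writes results/qc_report.csv and prints the removal
summary.
"""

from pathlib import Path

from meadowtherm.ingest import apply_qc, load_study, qc_report

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    dataset = load_study(DATA, window=(24, 31), years=[2010, 2011, 2012])
    cleaned, report = apply_qc(dataset)
    OUT.mkdir(exist_ok=True)
    report.to_csv(OUT / "qc_report.csv", index=False)
    print(qc_report(report).splitlines()[0])
    print(f"{report['days_kept'].sum():,} probe-days retained across "
          f"{len(report)} probes")


if __name__ == "__main__":
    main()
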