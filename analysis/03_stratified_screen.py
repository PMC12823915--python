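"""Stratified screening and volcano coordinates for the replicated drugs.

For each drug that cleared the replication gate, repeats the screen within
sex, age-band (20-69 / 70-99 years) and medication-count (<5 / >=5) strata
of each database, and emits the stratified table plus the volcano source
table (x = ln ROR, y = -log10 p, size = n11).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import dataclasses

from pvsignal.disprop import results_to_frame, screen
from pvsignal.icsr_io import EventTarget, read_plid
from pvsignal.stratify import stratified_screen, volcano_points
from pvsignal.synthetic import AF_PT_CODE, AF_PT_NAME

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
AF = EventTarget.of(AF_PT_CODE, [AF_PT_NAME])


def main():
    advanced = (ROOT / "advanced_drugs.txt").read_text().split()
    strat_rows, volcano_rows = [], []
    for db in ("JADER", "FAERS"):
        plid = read_plid(DATA / db / "plid.tsv")
        for drug in advanced:
            results, dropped = stratified_screen(plid, drug, AF)
            df = results_to_frame(results)
            df.insert(0, "database", db)
            strat_rows.append(df)
            overall = screen(plid, [drug], AF)
            pts, meta = volcano_points(overall + results)
            vdf = pd.DataFrame([dataclasses.asdict(p) for p in pts])
            vdf.insert(0, "drug", drug)
            vdf.insert(0, "database", db)
            volcano_rows.append(vdf)
            print(f"{db} {drug}: stratum exclusions {dict(dropped)}")

    strat = pd.concat(strat_rows, ignore_index=True)
    strat.to_csv(ROOT / "stratified.csv", index=False)
    cols = ["database", "drug", "variable", "level", "n11", "ROR", "fisher_p",
            "met_ROR", "met_PRR", "met_IC", "ic_strength", "excluded_low_count"]
    print("\nstratified screen:")
    print(strat[cols].round(3).to_string(index=False))

    vol = pd.concat(volcano_rows, ignore_index=True)
    vol.to_csv(ROOT / "volcano.csv", index=False)
    print(f"\nwrote {len(vol)} volcano points "
          "(reference lines: x = 0, y = 1.30103)")


if __name__ == "__main__":
    main()
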