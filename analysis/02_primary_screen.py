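"""Primary disproportionality screen of all eight drugs in both databases.

Reads the PLIDs written by 01_generate_data.py, screens every drug against
the rest of its database with the three metrics (ROR + Fisher, PRR + chi2,
BCPNN IC) under the pre-specified criteria, applies the cross-database
replication gate, and writes the per-drug screening tables — the machine
twin of a screening forest plot's source data — to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pvsignal.disprop import results_to_frame, screen
from pvsignal.icsr_io import EventTarget, read_plid
from pvsignal.pipeline import passes_replication_gate
from pvsignal.synthetic import AF_PT_CODE, AF_PT_NAME, OAB_DRUGS

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
AF = EventTarget.of(AF_PT_CODE, [AF_PT_NAME])


def main():
    per_db = {}
    for db in ("JADER", "FAERS"):
        plid = read_plid(DATA / db / "plid.tsv")
        results = screen(plid, OAB_DRUGS, AF)
        per_db[db] = {r.drug: r for r in results}
        df = results_to_frame(results)
        df.to_csv(ROOT / f"screen_{db}.csv", index=False)
        print(f"\n{db} primary screen:")
        cols = ["drug", "n11", "ROR", "ROR_lo", "fisher_p", "PRR_lo", "chi2",
                "IC_lo", "met_ROR", "met_PRR", "met_IC", "ic_strength"]
        print(df[cols].round(3).to_string(index=False))

    advanced = [d for d in OAB_DRUGS
                if passes_replication_gate(per_db["JADER"][d], per_db["FAERS"][d])]
    print(f"\nreplicated signals (advance to stratified/TTO): {advanced}")
    (ROOT / "advanced_drugs.txt").write_text("\n".join(advanced) + "\n")


if __name__ == "__main__":
    main()
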