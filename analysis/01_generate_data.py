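"""Generate the two synthetic databases used by the downstream analyses.

Draws one JADER-style and one FAERS-style extract at the study conditions
(20,000 cases each; reporting-rate ratio 3 planted for solifenacin and
mirabegron on atrial fibrillation; vibegron as rho = 1 negative control),
writes the dialect-formatted tables plus the integrated patient-level
dataset (PLID) under results/data/, and prints the realized versus expected
2x2 cell counts for the planted pairs.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pvsignal.icsr_io import build_plid, write_plid, write_tables
from pvsignal.pipeline import derive_seed
from pvsignal.synthetic import (
    default_synonyms,
    expected_contingency,
    generate,
    oab_af_config,
)

MASTER_SEED = 20260927
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main():
    for dialect, task in (("JADER", "gen_jader"), ("FAERS", "gen_faers")):
        cfg = oab_af_config(dialect, seed=derive_seed(MASTER_SEED, task))
        raw, truth = generate(cfg)
        outdir = OUT / dialect
        write_tables(raw, outdir)
        plid, log = build_plid(raw, synonyms=default_synonyms())
        write_plid(plid, outdir / "plid.tsv")
        print(f"\n{dialect}: {len(plid)} cases, {log.n_orphans} orphan records")
        ev = truth.events["Atrial fibrillation"]
        for drug in ("solifenacin", "mirabegron", "vibegron"):
            exp = truth.exposure[drug]
            realized = ((exp & ev).sum(), (exp & ~ev).sum(),
                        (~exp & ev).sum(), (~exp & ~ev).sum())
            expected = expected_contingency(cfg, drug, "Atrial fibrillation")
            print(f"  {drug:<12} realized n11..n22 {tuple(int(x) for x in realized)}"
                  f"  expected {tuple(round(x, 1) for x in expected)}")


if __name__ == "__main__":
    main()
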