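#!/usr/bin/env python
"""Infer per-gene kinetics from the simulated GRO measurements.

Aggregates triplicates by geometric mean, derives half-lives via the
steady-state relation HL = RA/TR, and reports the whole-Pol II
transcription rate per strain. Run 01_simulate_cohort.py first.
"""

import pathlib

import pandas as pd

from kisflux import gro, io

results = pathlib.Path(__file__).resolve().parent.parent / "results"
sample = io.read_tsv(results / "gro.tsv", io.GRO_COLUMNS)

tables = []
for strain, grp in sample.groupby("strain", sort=True):
    table = gro.build_kinetics_table(grp.drop(columns="strain"), strain)
    tables.append(table)
    total_tr = gro.total_polii_tr(table["TR"].dropna())
    print(f"{strain}: median HL {table['HL'].median():.3f} a.u., "
          f"total Pol II TR {total_tr:.0f} a.u./min "
          f"({table['HL'].isna().sum()} genes without defined HL)")

io.write_tsv(pd.concat(tables, ignore_index=True), results / "kinetics.tsv",
             io.KINETICS_COLUMNS)
print(f"wrote {results / 'kinetics.tsv'}")
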