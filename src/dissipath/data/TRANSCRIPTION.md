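# Fixture provenance

`table1.csv` and `table2.csv` transcribe the published 58-reaction summary of
steady-state performance parameters and dissipation for reversible 2/3/4-state
enzyme cycles, and the corresponding trade-off-variation optima (fold changes
in k_cat/K_m and k_cat at maximal dissipation).

Conventions applied during transcription:

- Thousands separators stripped; values printed like "4.4 x 10^-5" stored in
  scientific notation (`4.4e-5`).
- `generalist` reproduces the table's asterisks literally: exactly 8 enzymes
  (GPI, TIProRC, TIProR, KYNase_93D9, TM0831, FAProR, GI, GI3).  NSAARN, a
  promiscuous-substrate case, is unmarked in the source and stays unmarked.
- `boundary_case` in table2 marks the four reactions (CAII, KSI-D38E, AR, TAM)
  whose dissipation maximum was only reached after raising the ligand
  concentration (underlined in the source).

Known anomalies, preserved or corrected as noted:

- **CAII (rank 1)**: the printed row has J = 421,874, X/RT = 1.81 and
  phi/RT = 125,000, which is not their product (J*X = 763,592).  The row is
  shipped exactly as printed; it is excluded from the product-identity check
  and no intended value is guessed.
- **AR (rank 28)**: the printed J = 827 contradicts the same row's
  X/RT = 1.80 and phi/RT = 229 (827 * 1.80 = 1489), contradicts the row's
  position in the dissipation ordering, and is inconsistent with the
  trade-off optimum (977 * 1.79 = 1751).  phi/X = 127.2 restores the exact
  identity; `flux` stores 127.2 and this note records the printed 827.
- **PC1 (table2 rank 13)**: the printed optimal J = 60.6 does not reproduce
  the printed phi_max/RT = 1519 at X/RT = 11.37; transcribed as printed (no
  identity is asserted for table2 flux columns).
- Rows printing phi/RT to two significant figures (e.g. HcmABwt 0.163,
  EpiTmut 0.044) satisfy the product identity only within the printed
  precision; the loader's identity check accounts for half-ULP rounding of
  the three printed columns.
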