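"""Quantify a qPCR time course: Ct triplicates -> fold changes -> z-scores.

Simulates one study-design dataset (3 colonies x 7 timepoints every 4 h x
triplicate reactions, EF1a reference), runs the comparative-Ct chain and
prints the per-colony expression table and the cross-colony consensus for
the period gene.
"""

from antclock import (
    aggregate_colonies,
    expression_series,
    generate_qpcr_dataset,
    study_config,
)

ct = generate_qpcr_dataset(study_config(seed=1))
print(f"{len(ct)} Ct records ({ct['gene'].nunique()} genes, "
      f"{ct['colony'].nunique()} colonies, {ct['zt'].nunique()} timepoints)")

expr = expression_series(ct, reference_gene="EF1a")
per = expr[(expr["gene"] == "per") & (expr["colony"] == "colony1")]
print("\nperiod, colony1 (dCt -> fold -> z):")
print(per[["zt", "delta_ct", "fold", "zscore"]].round(3).to_string(index=False))

agg = aggregate_colonies(expr)
print("\nperiod, cross-colony consensus (mean z +/- SE over 3 colonies):")
print(agg[agg["gene"] == "per"].round(3).to_string(index=False))

# The z-scores express each colony's series in units of its own standard
# deviation, so colonies are comparable despite baseline Ct offsets; the
# fold column is the familiar 2^(-ddCt) relative quantity (values > 1 =
# above the gene's daily mean expression).
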