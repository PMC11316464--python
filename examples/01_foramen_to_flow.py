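"""From a femur's nutrient foramen to a blood-flow estimate.

Two adult specimens of one (imaginary) armadillo-sized taxon: one femur
with a single foramen, one with two foramina close together.  The chain is
minor diameter -> circular area -> summed area -> 20% arterial lumen ->
flow polynomial.
"""

from foramenflow import SpecimenRecord, aggregate_taxon

specimens = [
    SpecimenRecord(
        taxon="Dasypus_example",
        specimen_id="MNHN-1",
        foramen_minor_diameters=[0.62],   # mm
        femur_length=95.0,                # mm
        adult=True,
    ),
    SpecimenRecord(
        taxon="Dasypus_example",
        specimen_id="MNHN-2",
        foramen_minor_diameters=[0.45, 0.41],  # two foramina, areas summed
        femur_length=101.0,
        adult=True,
    ),
]

est = aggregate_taxon(specimens)
print(f"taxon:               {est.taxon}")
print(f"usable specimens:    {est.n_specimens}")
print(f"summed foramen area: {est.foramen_area_total:.4f} mm^2")
print(f"arterial lumen r:    {est.lumen_radius:.4f} mm   (20% of foramen area)")
print(f"blood flow Q̇:        {est.qdot:.3e} cm^3 s^-1")
print(f"legacy index Qi:     {est.qi:.3e} mm^3          (r^4/L)")
print()
print("Q̇ is the estimated volumetric flow through the femoral nutrient")
print("artery; the taxon value is the geometric mean over its specimens.")
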