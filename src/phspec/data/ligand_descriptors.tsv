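# Quantum-chemical descriptors of the myo-inositol phosphate ligands,
# packaged as reference data for report context only; phspec never
# recomputes them (they come from external DFT calculations).
# dipole moment in Debye, electronic spatial extent in Angstrom^2,
# single-point energies in atomic units (HF and MP2 levels).
ligand	dipole_moment_debye	electronic_spatial_extent_A2	energy_hf_au	energy_mp2_au
Ins(1,3,4)P3	17.2	10026	-2369.20	-2371.76
Ins(1,4,5)P3	11.7	9868	-2369.21	-2371.77
Ins(1,3,4,5)P4	10.6	13820	-2932.45	-2951.77
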