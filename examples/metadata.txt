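calibration_peak_ratio: 2.0
calibration_standard: CSA
concentration_mg_ml: 1.0
expression_tags: HHHHHH
instrument_name: synthetic-cd-1
mean_residue_weight_da: 119.37584879999987
molecular_weight_da: 14921.981099999985
n_residues: 126
pathlength_cm: 0.05
protein_class: soluble
sequence: HHHHHHCSQKKVCQFCMYRSRSMDTLMIEWSPKTMKLFCNVCVTGPESRICYKVQSSEILLAMERQWRIYKHWICLSELDQLHFNQWKETPRCHSTKTTIVGFQPDTETASSSQLRGSNLMNADFD
stated_interval_nm: 1.0
temperature_c: 25.0
uniprot_ids: SYN00001
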