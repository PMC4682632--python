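# Intrinsic deamidation half-times of Asn-X dipeptides in unstructured model
# peptides (pH 7.4, 37 C). Residue is the N+1 amino acid; t50 in days.
# Values are representative of pentapeptide-library measurements (Gly fastest,
# beta-branched aliphatics slowest). Edit or replace this file to use an
# alternative calibration: every computation takes the table as an argument.
# Pro is deliberately absent: the N+1 backbone nitrogen of proline is a
# tertiary amide and the succinimide pathway differs; sites with N+1 = Pro
# are reported with a missing t50 rather than an invented value.
#
# residue	t50_days	source
G	1.0	model-peptide library, pH 7.4, 37 C
H	9.7	model-peptide library, pH 7.4, 37 C
S	10.1	model-peptide library, pH 7.4, 37 C
A	22.4	model-peptide library, pH 7.4, 37 C
D	32.6	model-peptide library, pH 7.4, 37 C
C	54.3	model-peptide library, pH 7.4, 37 C
K	47.0	model-peptide library, pH 7.4, 37 C
R	58.0	model-peptide library, pH 7.4, 37 C
E	64.5	model-peptide library, pH 7.4, 37 C
T	73.5	model-peptide library, pH 7.4, 37 C
F	101.0	model-peptide library, pH 7.4, 37 C
N	127.0	model-peptide library, pH 7.4, 37 C
Q	138.0	model-peptide library, pH 7.4, 37 C
M	142.0	model-peptide library, pH 7.4, 37 C
Y	151.0	model-peptide library, pH 7.4, 37 C
W	168.0	model-peptide library, pH 7.4, 37 C
V	319.0	model-peptide library, pH 7.4, 37 C
L	451.0	model-peptide library, pH 7.4, 37 C
I	507.0	model-peptide library, pH 7.4, 37 C
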