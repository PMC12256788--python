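format-version: 1.2
ontology: mitotriage-fixture
remark: Synthetic stand-in phenotype ontology for worked examples and tests. Term ids use the FX namespace; the shape (multi-system branches, two diamonds, one obsolete term) mimics the regions of a clinical phenotype ontology relevant to mitochondrial disease. Not derived from any real ontology release.

[Term]
id: FX:0000001
name: Phenotypic abnormality

[Term]
id: FX:0000010
name: Abnormality of the nervous system
is_a: FX:0000001

[Term]
id: FX:0000011
name: Seizure
is_a: FX:0000010

[Term]
id: FX:0000012
name: Generalized tonic-clonic seizure
is_a: FX:0000011

[Term]
id: FX:0000013
name: Focal seizure
is_a: FX:0000011

[Term]
id: FX:0000014
name: Focal myoclonic seizure
is_a: FX:0000013
is_a: FX:0000015

[Term]
id: FX:0000015
name: Myoclonus
is_a: FX:0000010

[Term]
id: FX:0000016
name: Encephalopathy
is_a: FX:0000010

[Term]
id: FX:0000017
name: Stroke-like episode
is_a: FX:0000016

[Term]
id: FX:0000018
name: Ataxia
is_a: FX:0000010

[Term]
id: FX:0000019
name: Gait ataxia
is_a: FX:0000018

[Term]
id: FX:0000020
name: Developmental regression
is_a: FX:0000010

[Term]
id: FX:0000021
name: Peripheral neuropathy
is_a: FX:0000010

[Term]
id: FX:0000022
name: Axonal sensorimotor neuropathy
is_a: FX:0000021

[Term]
id: FX:0000025
name: Cognitive impairment
is_a: FX:0000010

[Term]
id: FX:0000026
name: Intellectual disability
is_a: FX:0000025

[Term]
id: FX:0000027
name: Migraine
is_a: FX:0000010

[Term]
id: FX:0000030
name: Abnormality of the eye
is_a: FX:0000001

[Term]
id: FX:0000031
name: Ophthalmoplegia
is_a: FX:0000030

[Term]
id: FX:0000032
name: Progressive external ophthalmoplegia
is_a: FX:0000031

[Term]
id: FX:0000033
name: Ptosis
is_a: FX:0000030

[Term]
id: FX:0000034
name: Optic atrophy
is_a: FX:0000030

[Term]
id: FX:0000035
name: Bilateral optic atrophy
is_a: FX:0000034

[Term]
id: FX:0000036
name: Retinopathy
is_a: FX:0000030

[Term]
id: FX:0000037
name: Pigmentary retinopathy
is_a: FX:0000036

[Term]
id: FX:0000040
name: Abnormality of the ear
is_a: FX:0000001

[Term]
id: FX:0000041
name: Hearing impairment
is_a: FX:0000040

[Term]
id: FX:0000042
name: Sensorineural hearing impairment
is_a: FX:0000041

[Term]
id: FX:0000043
name: Progressive sensorineural hearing impairment
is_a: FX:0000042

[Term]
id: FX:0000050
name: Abnormality of the musculature
is_a: FX:0000001

[Term]
id: FX:0000051
name: Myopathy
is_a: FX:0000050

[Term]
id: FX:0000052
name: Mitochondrial myopathy
is_a: FX:0000051

[Term]
id: FX:0000053
name: Proximal muscle weakness
is_a: FX:0000051
is_a: FX:0000055

[Term]
id: FX:0000054
name: Exercise intolerance
is_a: FX:0000050

[Term]
id: FX:0000055
name: Muscle weakness
is_a: FX:0000050

[Term]
id: FX:0000056
name: Hypotonia
is_a: FX:0000050

[Term]
id: FX:0000060
name: Abnormality of metabolism
is_a: FX:0000001

[Term]
id: FX:0000061
name: Lactic acidosis
is_a: FX:0000060

[Term]
id: FX:0000062
name: Elevated cerebrospinal fluid lactate
is_a: FX:0000060

[Term]
id: FX:0000063
name: Diabetes mellitus
is_a: FX:0000060

[Term]
id: FX:0000064
name: Insulin-dependent diabetes mellitus
is_a: FX:0000063

[Term]
id: FX:0000070
name: Abnormality of the cardiovascular system
is_a: FX:0000001

[Term]
id: FX:0000071
name: Cardiomyopathy
is_a: FX:0000070

[Term]
id: FX:0000072
name: Hypertrophic cardiomyopathy
is_a: FX:0000071

[Term]
id: FX:0000073
name: Dilated cardiomyopathy
is_a: FX:0000071

[Term]
id: FX:0000074
name: Cardiac conduction abnormality
is_a: FX:0000070

[Term]
id: FX:0000075
name: Ventricular preexcitation
is_a: FX:0000074

[Term]
id: FX:0000080
name: Abnormality of the digestive system
is_a: FX:0000001

[Term]
id: FX:0000081
name: Dysphagia
is_a: FX:0000080

[Term]
id: FX:0000082
name: Intestinal pseudo-obstruction
is_a: FX:0000080

[Term]
id: FX:0000083
name: Hepatopathy
is_a: FX:0000080

[Term]
id: FX:0000090
name: Growth abnormality
is_a: FX:0000001

[Term]
id: FX:0000091
name: Short stature
is_a: FX:0000090

[Term]
id: FX:0000092
name: Failure to thrive
is_a: FX:0000090

[Term]
id: FX:0000095
name: Abnormality of the kidney
is_a: FX:0000001

[Term]
id: FX:0000096
name: Renal tubular dysfunction
is_a: FX:0000095

[Term]
id: FX:0000097
name: Fatigue
is_a: FX:0000001

[Term]
id: FX:0000099
name: obsolete Deafness
is_obsolete: true
replaced_by: FX:0000041
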