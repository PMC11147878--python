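phoneme	class	place	manner	voicing	height	backness
P	consonant	bilabial	stop	voiceless
B	consonant	bilabial	stop	voiced
T	consonant	alveolar	stop	voiceless
D	consonant	alveolar	stop	voiced
K	consonant	velar	stop	voiceless
G	consonant	velar	stop	voiced
CH	consonant	postalveolar	affricate	voiceless
JH	consonant	postalveolar	affricate	voiced
F	consonant	labiodental	fricative	voiceless
V	consonant	labiodental	fricative	voiced
TH	consonant	dental	fricative	voiceless
DH	consonant	dental	fricative	voiced
S	consonant	alveolar	fricative	voiceless
Z	consonant	alveolar	fricative	voiced
SH	consonant	postalveolar	fricative	voiceless
ZH	consonant	postalveolar	fricative	voiced
HH	consonant	glottal	fricative	voiceless
M	consonant	bilabial	nasal	voiced
N	consonant	alveolar	nasal	voiced
NG	consonant	velar	nasal	voiced
L	consonant	alveolar	lateral	voiced
R	consonant	alveolar	approximant	voiced
W	consonant	labiovelar	approximant	voiced
Y	consonant	palatal	approximant	voiced
IY	vowel			voiced	high	front
IH	vowel			voiced	high	front
EY	vowel			voiced	mid	front
EH	vowel			voiced	mid	front
AE	vowel			voiced	low	front
AA	vowel			voiced	low	back
AO	vowel			voiced	mid	back
OW	vowel			voiced	mid	back
UH	vowel			voiced	high	back
UW	vowel			voiced	high	back
AH	vowel			voiced	mid	central
ER	vowel			voiced	mid	central
AY	vowel			voiced	low	front
AW	vowel			voiced	low	back
OY	vowel			voiced	mid	back
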