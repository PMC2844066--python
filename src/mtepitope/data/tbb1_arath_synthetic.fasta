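>TBB1_ARATH_SYNTHETIC synthetic stand-in for A. thaliana beta-tubulin 1 (TBB1; 447 aa; published epitope regions verbatim)
MREILHVQGGQCGNQIGAKFWEVISDEHGIDPGGTYHGDSDLQLDRISVYANEALGGKYV
PRAILVNLEPGTMDSVRSRPPYGQIFRPDNFVFGQGMGNNWGKGHVTIGAEKVDSVLSVV
RKEAESCDCLQGFNLTHSLGGGTGSGNGTPLKSKIREEYPDRAMNTFSVLPSCKVWDTVR
EPLNATLSVHQLVENTDVTYDIDNRALYDICFRTLKLTTLTCGDLNHWVSATMSGVITCL
RFPGQLTADLRKLAVNMVYFPRLHFFMPGFAPLTVNGSQQYRALTVPVHTQQVFDAKNMM
AACDPRHGRYFTVAAVFRGRMAMQEVDEQMFNVQDKNSSYFVGIIPNNDKTAVCDTPCEG
LKMAVAFIGNSTAIQELFKRISPQFTAMFRRKALLNWYTGEGMDEMEFKEAESIMNDLVS
EYQQYYQDATADEEDEYDEEEEQVYES
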