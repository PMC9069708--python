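Sod1	oxidative stress
Sod2	oxidative stress
Cat	oxidative stress
Gpx1	oxidative stress
Sirt1	aging/longevity
Sirt6	aging/longevity
Sirt7	aging/longevity
Foxo3	aging/longevity
Foxo3	autophagy
Igf1r	aging/longevity
Jund	transcription factor
Cbx3	transcription factor
Pim1	transcription factor
Sox11	transcription factor
Klf12	transcription factor
Mcm6	DNA damage/repair
H2afx	DNA damage/repair
Mgmt	DNA damage/repair
Sirt6	DNA damage/repair
Tdg	DNA damage/repair
Rragb	autophagy
Gsk3b	autophagy
Fbxw7	autophagy
Stk11	autophagy
Myo7a	stereocilia
Myo6	stereocilia
Myo15	stereocilia
Espn	stereocilia
Eps8	stereocilia
Tmc1	ion channel
Tmc1	stereocilia
Kcnq4	ion channel
Cacna1d	ion channel
Clic3	ion channel
Otof	synapse
Slc17a8	synapse
Chrna9	synapse
Chrna10	synapse
Slc26a5	ion channel
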