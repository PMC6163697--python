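dimension,level
daynight,day
daynight,night
age,0-4
age,5-9
age,10-14
inhabitants,rural (<2000 inhab.)
inhabitants,2000-4999 inhab.
inhabitants,5000-9999 inhab.
inhabitants,10000-19999 inhab.
inhabitants,20000-49999 inhab.
inhabitants,50000-99999 inhab.
inhabitants,100000-199999 inhab.
inhabitants,200000-1999999 inhab.
substation,>=40 m
substation,<40 m
substation,same building or adjacent
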