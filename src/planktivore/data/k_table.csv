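species,year,k
mackerel,2005,0.34
mackerel,2006,0.24
mackerel,2007,0.47
mackerel,2008,0.36
mackerel,2009,0.19
mackerel,2010,0.16
herring,2005,0.15
herring,2006,0.15
herring,2007,0.19
herring,2008,0.17
herring,2009,0.17
herring,2010,0.24
blue_whiting,2005,0.19
blue_whiting,2006,0.19
blue_whiting,2007,0.19
blue_whiting,2008,0.26
blue_whiting,2009,0.07
blue_whiting,2010,0.24
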