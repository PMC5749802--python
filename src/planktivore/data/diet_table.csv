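species,year,season,copepods,euphausiids,amphipods,other_crustaceans,appendicularians,fish,other,source
mackerel,2005,July,72,4,4,1,14,1,4,observed
mackerel,2006,July,89,2,<1,4,4,0,2,observed
mackerel,2007,July,67,<1,2,0,30,0,1,observed
mackerel,2008,July,61,6,2,11,18,<1,3,filled
mackerel,2009,July,26,12,1,50,9,0,2,observed
mackerel,2010,July,50,11,1,<1,31,1,6,observed
herring,2005,May,91,3,1,0,5,0,<1,observed
herring,2005,July,73,10,2,5,9,0,<1,observed
herring,2006,May,92,7,<1,0,1,0,<1,observed
herring,2006,July,53,13,10,2,21,0,<1,filled
herring,2007,May,41,7,4,1,47,0,1,observed
herring,2007,July,53,13,10,2,21,0,<1,filled
herring,2008,May,42,6,3,1,48,<1,<1,observed
herring,2008,July,31,6,3,<1,60,0,0,observed
herring,2009,May,61,4,<1,0,32,0,3,observed
herring,2009,July,48,30,22,0,<1,0,<1,observed
herring,2010,May,82,2,4,0,0,0,13,observed
herring,2010,July,61,8,12,4,15,0,1,observed
blue_whiting,2005,May,73,23,3,0,<1,0,0,observed
blue_whiting,2005,July,17,63,19,1,1,0,<1,filled
blue_whiting,2006,May,33,48,6,0,7,2,4,observed
blue_whiting,2006,July,17,63,19,1,1,0,<1,filled
blue_whiting,2007,May,33,55,7,0,0,3,2,observed
blue_whiting,2007,July,2,88,8,0,1,0,1,observed
blue_whiting,2008,May,39,46,3,0,0,11,<1,observed
blue_whiting,2008,July,17,63,19,1,1,0,<1,filled
blue_whiting,2009,May,0,93,6,0,0,0,0,observed
blue_whiting,2009,July,17,63,19,1,1,0,<1,filled
blue_whiting,2010,May,4,67,26,0,0,2,1,observed
blue_whiting,2010,July,32,38,29,1,0,0,0,observed
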