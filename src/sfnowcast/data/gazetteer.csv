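kind,name,state
code,AK,AK
state,Alaska,AK
code,AL,AL
state,Alabama,AL
code,AR,AR
state,Arkansas,AR
code,AZ,AZ
state,Arizona,AZ
code,CA,CA
state,California,CA
code,CO,CO
state,Colorado,CO
code,CT,CT
state,Connecticut,CT
code,DC,DC
state,District of Columbia,DC
code,DE,DE
state,Delaware,DE
code,FL,FL
state,Florida,FL
code,GA,GA
state,Georgia,GA
code,HI,HI
state,Hawaii,HI
code,IA,IA
state,Iowa,IA
code,ID,ID
state,Idaho,ID
code,IL,IL
state,Illinois,IL
code,IN,IN
state,Indiana,IN
code,KS,KS
state,Kansas,KS
code,KY,KY
state,Kentucky,KY
code,LA,LA
state,Louisiana,LA
code,MA,MA
state,Massachusetts,MA
code,MD,MD
state,Maryland,MD
code,ME,ME
state,Maine,ME
code,MI,MI
state,Michigan,MI
code,MN,MN
state,Minnesota,MN
code,MO,MO
state,Missouri,MO
code,MS,MS
state,Mississippi,MS
code,MT,MT
state,Montana,MT
code,NC,NC
state,North Carolina,NC
code,ND,ND
state,North Dakota,ND
code,NE,NE
state,Nebraska,NE
code,NH,NH
state,New Hampshire,NH
code,NJ,NJ
state,New Jersey,NJ
code,NM,NM
state,New Mexico,NM
code,NV,NV
state,Nevada,NV
code,NY,NY
state,New York,NY
code,OH,OH
state,Ohio,OH
code,OK,OK
state,Oklahoma,OK
code,OR,OR
state,Oregon,OR
code,PA,PA
state,Pennsylvania,PA
code,RI,RI
state,Rhode Island,RI
code,SC,SC
state,South Carolina,SC
code,SD,SD
state,South Dakota,SD
code,TN,TN
state,Tennessee,TN
code,TX,TX
state,Texas,TX
code,UT,UT
state,Utah,UT
code,VA,VA
state,Virginia,VA
code,VT,VT
state,Vermont,VT
code,WA,WA
state,Washington,WA
code,WI,WI
state,Wisconsin,WI
code,WV,WV
state,West Virginia,WV
code,WY,WY
state,Wyoming,WY
city,akron,OH
city,albany,NY
city,albuquerque,NM
city,anchorage,AK
city,ann arbor,MI
city,arlington,TX
city,atlanta,GA
city,augusta,ME
city,aurora,CO
city,austin,TX
city,bakersfield,CA
city,baltimore,MD
city,bangor,ME
city,baton rouge,LA
city,billings,MT
city,birmingham,AL
city,bismarck,ND
city,boise,ID
city,boston,MA
city,boulder,CO
city,brooklyn,NY
city,buffalo,NY
city,burlington,VT
city,casper,WY
city,charleston,WV
city,charlotte,NC
city,chattanooga,TN
city,cheyenne,WY
city,chicago,IL
city,cincinnati,OH
city,cleveland,OH
city,colorado springs,CO
city,concord,NH
city,dallas,TX
city,denver,CO
city,des moines,IA
city,detroit,MI
city,dover,DE
city,duluth,MN
city,durham,NC
city,el paso,TX
city,eugene,OR
city,fargo,ND
city,flint,MI
city,fort collins,CO
city,fort worth,TX
city,fresno,CA
city,grand rapids,MI
city,greeley,CO
city,greensboro,NC
city,gulfport,MS
city,hartford,CT
city,honolulu,HI
city,houston,TX
city,huntington,WV
city,indianapolis,IN
city,jackson,MS
city,jacksonville,FL
city,jersey city,NJ
city,kansas city,MO
city,knoxville,TN
city,lafayette,LA
city,lake charles,LA
city,lakewood,CO
city,lansing,MI
city,las vegas,NV
city,little rock,AR
city,long beach,CA
city,los angeles,CA
city,louisville,KY
city,macon,GA
city,manchester,NH
city,manhattan,NY
city,memphis,TN
city,mesa,AZ
city,metairie,LA
city,miami,FL
city,milwaukee,WI
city,minneapolis,MN
city,missoula,MT
city,mobile,AL
city,montgomery,AL
city,montpelier,VT
city,nashville,TN
city,new haven,CT
city,new orleans,LA
city,new york city,NY
city,newark,NJ
city,norfolk,VA
city,oakland,CA
city,ogden,UT
city,oklahoma city,OK
city,omaha,NE
city,orlando,FL
city,philadelphia,PA
city,phoenix,AZ
city,pittsburgh,PA
city,providence,RI
city,provo,UT
city,pueblo,CO
city,queens,NY
city,raleigh,NC
city,rapid city,SD
city,reno,NV
city,richmond,VA
city,rochester,NY
city,sacramento,CA
city,salem,OR
city,salt lake city,UT
city,san antonio,TX
city,san diego,CA
city,san francisco,CA
city,san jose,CA
city,sandy,UT
city,santa fe,NM
city,savannah,GA
city,scottsdale,AZ
city,seattle,WA
city,shreveport,LA
city,sioux falls,SD
city,spokane,WA
city,st george,UT
city,st louis,MO
city,st paul,MN
city,syracuse,NY
city,tacoma,WA
city,tampa,FL
city,tempe,AZ
city,toledo,OH
city,topeka,KS
city,trenton,NJ
city,tucson,AZ
city,tulsa,OK
city,virginia beach,VA
city,washington dc,DC
city,west valley city,UT
city,wichita,KS
city,wilmington,DE
city,yonkers,NY
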