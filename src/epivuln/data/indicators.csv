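code,label,orientation,nature,relations,paper_selection
X1,population per 1 km2,destimulant,D,intended|unintended,accept
X2,share of population aged 6-19 years (%),destimulant,D,intended,accept
X3,share of population aged 60 and over (%),destimulant,D,intended|unintended,reject
X4,population per township,destimulant,D,unintended,reject
X5,balance of internal migration per 1000 population,destimulant,D,intended|unintended,accept
X6,balance of foreign migration per 1000 population,destimulant,D,intended|unintended,accept
X7,registered unemployment rate (%),stimulant,E,intended,accept
X8,average number of persons per 1 apartment,destimulant,S,intended,reject
X9,average number of persons per 1 room,destimulant,S,intended,accept
X10,number of accommodation establishments over 10 people,destimulant,E,intended|unintended,reject
X11,number of vehicles per 1000 population,destimulant,E,intended,accept
X12,hypermarkets (number),destimulant,E,unintended,accept
X13,supermarkets (number),destimulant,E,unintended,reject
X14,marketplaces (number),destimulant,E,unintended,accept
X15,village centers (number),destimulant,S,intended,reject
X16,events (number),destimulant,S,intended,reject
X17,number of event attendees per 1000 population,destimulant,S,intended,accept
X18,"number of people per facility (cultural center, community center, club, community hall)",destimulant,S,intended,accept
X19,number of beds in sanatoria,destimulant,S,intended,reject
X20,population density in housing areas (person/1 km2),destimulant,L,unintended,accept
X21,population density of built-up and urbanized areas (person/km2),destimulant,L,unintended,accept
X22,average useful floor area of a dwelling per 1 person,stimulant,S,intended,reject
X23,population density of industrial areas (person/1 km2),destimulant,L,intended|unintended,accept
X24,number of towns,destimulant,L,unintended,accept
X25,business entities by size classes per 1000 inhabitants in total,destimulant,E,intended|unintended,accept
X26,ambulatory health care - medical consultations per 1000 population,destimulant,S,intended,reject
X27,physicians (total working staff) per 10000 population,destimulant,S,intended,accept
X28,residents of nursing homes per 1000 inhabitants,destimulant,S,intended,accept
X29,children in pre-school education establishments per 1000 children aged 3-5 years,destimulant,S,intended,accept
X30,national economy entities employing more than 49 persons per 10 thousand population,destimulant,E,intended|unintended,reject
X31,number of bed places per 1000 population,destimulant,E,intended|unintended,reject
X32,tourists using accommodation per 1000 population,destimulant,E,intended,accept
X33,degree of utilisation of accommodation (%),destimulant,E,intended|unintended,accept
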