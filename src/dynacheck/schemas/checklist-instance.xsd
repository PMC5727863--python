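<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="checklist">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="problem" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="item" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="text" type="xs:string"/>
                    <xs:element name="bind" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="slot" type="xs:string" use="required"/>
                        <xs:attribute name="kind" use="required">
                          <xs:simpleType>
                            <xs:restriction base="xs:string">
                              <xs:enumeration value="number"/>
                              <xs:enumeration value="boolean"/>
                              <xs:enumeration value="text"/>
                              <xs:enumeration value="date"/>
                            </xs:restriction>
                          </xs:simpleType>
                        </xs:attribute>
                        <xs:attribute name="value" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="material" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="kind" type="xs:string" use="required"/>
                        <xs:attribute name="payload" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="state" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="unchecked"/>
                        <xs:enumeration value="checked"/>
                        <xs:enumeration value="auto_checked"/>
                        <xs:enumeration value="not_applicable"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                  <xs:attribute name="flags" type="xs:string"/>
                  <xs:attribute name="provenance" type="xs:string"/>
                  <xs:attribute name="options" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="description" type="xs:string"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="audit" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="instance_id" type="xs:string" use="required"/>
      <xs:attribute name="form_id" type="xs:string" use="required"/>
      <xs:attribute name="patient_id" type="xs:string" use="required"/>
      <xs:attribute name="generated_at" type="xs:integer" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
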